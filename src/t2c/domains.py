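"""TAD boundaries and point loops on a binned contact matrix.

Boundaries are called with the insulation-square method: the raw
insulation value at bin *i* is the mean count in the w x w window of
pixels linking the w bins ending at *i* with the w bins starting at
*i*+1; a bin sitting between two domains has few such cross-contacts and
shows a local minimum.  The score is normalised as log2(value / mean over
defined bins), so 0 means average insulation and negative values mean
depletion.

Loops are focal off-diagonal enrichments: a pixel is a loop candidate if
its count clears an absolute floor, a fold over the distance-decay
expectation, and the same fold over its local 8-neighbourhood mean;
touching candidates are merged to the strongest pixel.  Short-range
pixels (|i-j| <= 1) are dominated by self- and re-ligation products and
are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import BinAxis, ContactMatrix
from .intervals import GenomicInterval

MIN_LOOP_SEPARATION = 2  # pixels with |i-j| < 2 are ignored everywhere


@dataclass
class InsulationProfile:
    """Per-bin insulation values and normalised scores.

    ``defined[i]`` is False for the first and last ``window`` bins, where
    the full w x w square does not fit.  A raw value of 0 at a defined bin
    gives a normalised score of -inf (maximal insulation).
    """

    raw: np.ndarray
    score: np.ndarray
    defined: np.ndarray
    window: int
    axis: BinAxis

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for i in np.flatnonzero(self.defined):
                iv = self.axis.bin_interval(int(i))
                s = self.score[i]
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s:.6g}\n")


@dataclass(frozen=True)
class BoundaryCall:
    """A domain boundary: a strict local minimum of the insulation score."""

    bin_index: int
    position: int  # genomic coordinate of the boundary bin edge
    depth: float  # normalised score at the minimum


@dataclass(frozen=True)
class LoopCall:
    """A focal contact between two distal anchors."""

    anchor_i: GenomicInterval
    anchor_j: GenomicInterval
    bin_i: int
    bin_j: int
    observed: float
    expected: float

    @property
    def enrichment(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("inf")

    @property
    def span(self) -> int:
        return self.anchor_j.start - self.anchor_i.start


def insulation_profile(bm: ContactMatrix, window_bins: int = 5) -> InsulationProfile:
    """Insulation values for every bin of a binned matrix.

    Raw value at bin i = mean of M[a, b] for a in (i-w, i], b in (i, i+w].
    Defined for w-1 <= i <= n-1-w.
    """
    if not bm.is_binned:
        raise ValueError("insulation requires a binned matrix")
    if window_bins < 1:
        raise ValueError("window must be >= 1")
    n = bm.n
    if n <= 2 * window_bins:
        raise ValueError(f"matrix with {n} bins too small for window {window_bins}")
    w = window_bins
    m = bm.dense().astype(float)
    # summed-area table for O(1) rectangle sums
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = m.cumsum(0).cumsum(1)
    raw = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for i in range(w - 1, n - w):
        a0, a1 = i - w + 1, i + 1  # rows [a0, a1)
        b0, b1 = i + 1, i + w + 1  # cols [b0, b1)
        total = sat[a1, b1] - sat[a0, b1] - sat[a1, b0] + sat[a0, b0]
        raw[i] = total / (w * w)
        defined[i] = True
    mean = np.nanmean(raw[defined]) if defined.any() else np.nan
    score = np.full(n, np.nan)
    if defined.any() and mean > 0:
        with np.errstate(divide="ignore"):
            score[defined] = np.log2(raw[defined] / mean)
    else:
        defined[:] = False  # zero-mean degenerate case: all undefined
    axis: BinAxis = bm.axis
    return InsulationProfile(raw, score, defined, w, axis)


def call_boundaries(profile: InsulationProfile, delta: float = 0.5) -> list[BoundaryCall]:
    """Strict local minima of the normalised score at least ``delta`` below 0.

    A flat run of equal minimal values counts once, at its leftmost bin,
    provided the run is strictly below both neighbours.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    score = profile.score
    idx = np.flatnonzero(profile.defined)
    calls: list[BoundaryCall] = []
    k = 0
    while k < len(idx):
        i = idx[k]
        # extend a flat run of equal scores
        k2 = k
        while k2 + 1 < len(idx) and idx[k2 + 1] == idx[k2] + 1 and score[idx[k2 + 1]] == score[i]:
            k2 += 1
        left_ok = k == 0 or score[idx[k - 1]] > score[i]
        right_ok = k2 == len(idx) - 1 or score[idx[k2 + 1]] > score[i]
        interior = k > 0 and k2 < len(idx) - 1  # edge bins are not minima
        if interior and left_ok and right_ok and score[i] <= -delta:
            axis = profile.axis
            pos = axis.bin_interval(int(i)).end  # boundary sits at the bin's right edge
            calls.append(BoundaryCall(int(i), pos, float(score[i])))
        k = k2 + 1
    return calls


def expected_by_distance(bm: ContactMatrix) -> np.ndarray:
    """Mean count at each bin separation d = 0..n-1, zeros included."""
    if not bm.is_binned:
        raise ValueError("expected profile requires a binned matrix")
    m = bm.dense().astype(float)
    n = bm.n
    return np.array([np.mean(np.diagonal(m, offset=d)) for d in range(n)])


def call_loops(
    bm: ContactMatrix,
    min_separation_bins: int = 3,
    enrichment_threshold: float = 3.0,
    min_count: float = 5,
    neighborhood: int = 1,
) -> list[LoopCall]:
    """Call focal loops on a binned matrix.

    A pixel (i, j) with j - i >= min_separation is a candidate iff

    * observed >= min_count,
    * observed / expected(j - i) >= enrichment_threshold, and
    * observed > enrichment_threshold x mean of its 8-neighbourhood
      (``neighborhood`` = Chebyshev radius; diagonal-adjacent pixels with
      separation < 2 are excluded from the neighbourhood mean).

    Touching candidates (8-connectivity) are merged to the pixel with the
    highest observed/expected enrichment.
    """
    if min_separation_bins < MIN_LOOP_SEPARATION:
        raise ValueError(f"min_separation_bins must be >= {MIN_LOOP_SEPARATION}")
    if enrichment_threshold <= 0 or min_count <= 0:
        raise ValueError("thresholds must be positive")
    m = bm.dense().astype(float)
    n = bm.n
    exp = expected_by_distance(bm)
    candidates: list[tuple[int, int, float, float]] = []
    for i in range(n):
        for j in range(i + min_separation_bins, n):
            obs = m[i, j]
            if obs < min_count:
                continue
            e = exp[j - i]
            if e <= 0 or obs / e < enrichment_threshold:
                continue
            neigh = []
            for a in range(max(0, i - neighborhood), min(n, i + neighborhood + 1)):
                for b in range(max(0, j - neighborhood), min(n, j + neighborhood + 1)):
                    if (a, b) == (i, j) or abs(a - b) < MIN_LOOP_SEPARATION:
                        continue
                    neigh.append(m[a, b])
            if neigh and obs <= enrichment_threshold * float(np.mean(neigh)):
                continue
            candidates.append((i, j, obs, e))
    # merge 8-connected candidate clusters to the maximal-enrichment pixel
    merged: list[tuple[int, int, float, float]] = []
    used = [False] * len(candidates)
    for k, cand in enumerate(candidates):
        if used[k]:
            continue
        cluster = [k]
        used[k] = True
        queue = [k]
        while queue:
            a = queue.pop()
            for b, other in enumerate(candidates):
                if not used[b] and max(
                    abs(candidates[a][0] - other[0]), abs(candidates[a][1] - other[1])
                ) <= 1:
                    used[b] = True
                    cluster.append(b)
                    queue.append(b)
        best = max(
            cluster,
            key=lambda q: (
                candidates[q][2] / candidates[q][3],
                -candidates[q][0],
                -candidates[q][1],
            ),
        )
        merged.append(candidates[best])
    axis: BinAxis = bm.axis
    calls = [
        LoopCall(
            axis.bin_interval(i), axis.bin_interval(j), i, j, obs, e
        )
        for i, j, obs, e in sorted(merged)
    ]
    return calls


def write_boundaries_bed(calls: list[BoundaryCall], axis: BinAxis, path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            iv = axis.bin_interval(c.bin_index)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tboundary\t{c.depth:.4g}\n")


def write_loops_bedpe(calls: list[LoopCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tobserved\texpected\tenrichment\n"
        )
        for c in calls:
            fh.write(
                f"{c.anchor_i.chrom}\t{c.anchor_i.start}\t{c.anchor_i.end}"
                f"\t{c.anchor_j.chrom}\t{c.anchor_j.start}\t{c.anchor_j.end}"
                f"\t{c.observed:g}\t{c.expected:.6g}\t{c.enrichment:.4g}\n"
            )
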