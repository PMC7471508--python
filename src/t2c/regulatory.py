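"""Enhancer-candidate calling inside a distal loop anchor.

A loop anchor that lands in a gene desert is a candidate regulatory
region; within it, clusters of H3K27ac peaks supported by sequence
conservation are the enhancer candidates.  Peaks overlapping the anchor
(any overlap — a peak straddling the anchor edge is kept whole) are
merged when closer than a gap threshold, scored by mean conservation and
named Enh1..n from left to right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .intervals import GenomicInterval


@dataclass(frozen=True)
class Peak:
    """A called peak (e.g. H3K27ac) with an optional signal value."""

    interval: GenomicInterval
    signal: float | None = None


@dataclass
class ConservationTrack:
    """Stepwise scores with bedGraph semantics: sorted, non-overlapping intervals."""

    intervals: list[GenomicInterval]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.scores):
            raise ValueError("intervals and scores differ in length")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"track intervals overlap or are unsorted near {a}")

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        ivs, scores = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}: line {lineno}: need 4 bedGraph columns")
                ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
                scores.append(float(parts[3]))
        order = sorted(range(len(ivs)), key=lambda k: (ivs[k].chrom, ivs[k].start))
        return cls([ivs[k] for k in order], [scores[k] for k in order])

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for iv, s in zip(self.intervals, self.scores):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s:g}\n")


@dataclass(frozen=True)
class EnhancerCandidate:
    """A merged, conservation-supported peak cluster within a loop anchor."""

    name: str
    interval: GenomicInterval
    n_peaks: int
    mean_conservation: float


def mean_conservation(interval: GenomicInterval, cons: ConservationTrack) -> float:
    """Length-weighted mean track score over an interval; uncovered bases score 0."""
    total = 0.0
    for iv, s in zip(cons.intervals, cons.scores):
        if iv.chrom != interval.chrom:
            continue
        lo = max(iv.start, interval.start)
        hi = min(iv.end, interval.end)
        if hi > lo:
            total += s * (hi - lo)
    return total / len(interval)


def merge_intervals(ivs: list[GenomicInterval], merge_gap: int) -> list[list[GenomicInterval]]:
    """Group sorted same-chromosome intervals whose gaps are <= merge_gap."""
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    ivs = sorted(ivs, key=lambda v: (v.start, v.end))
    clusters: list[list[GenomicInterval]] = []
    for iv in ivs:
        if clusters and iv.start - max(v.end for v in clusters[-1]) <= merge_gap:
            clusters[-1].append(iv)
        else:
            clusters.append([iv])
    return clusters


def call_enhancer_candidates(
    anchor: GenomicInterval,
    peaks: list[Peak],
    cons: ConservationTrack | None = None,
    merge_gap: int = 2000,
    min_cons: float = 0.0,
    truncate_to_anchor: bool = False,
) -> list[EnhancerCandidate]:
    """Cluster anchor-overlapping peaks into named enhancer candidates.

    Peaks with any overlap with the anchor are selected whole (set
    ``truncate_to_anchor`` to clip them to the anchor instead), merged when
    separated by <= ``merge_gap`` bp, filtered to mean conservation >=
    ``min_cons`` and named Enh1..n left to right.  With no track given,
    conservation is reported as 0 and not filtered on.
    """
    selected = [p.interval for p in peaks if p.interval.overlaps(anchor)]
    if truncate_to_anchor:
        selected = [
            GenomicInterval(
                iv.chrom, max(iv.start, anchor.start), min(iv.end, anchor.end)
            )
            for iv in selected
        ]
    candidates: list[EnhancerCandidate] = []
    for cluster in merge_intervals(selected, merge_gap):
        iv = GenomicInterval(
            cluster[0].chrom,
            min(v.start for v in cluster),
            max(v.end for v in cluster),
        )
        mc = mean_conservation(iv, cons) if cons is not None else 0.0
        if cons is not None and mc < min_cons:
            continue
        candidates.append(EnhancerCandidate("", iv, len(cluster), mc))
    candidates.sort(key=lambda c: c.interval.start)
    return [
        EnhancerCandidate(f"Enh{k}", c.interval, c.n_peaks, c.mean_conservation)
        for k, c in enumerate(candidates, start=1)
    ]


def write_candidates(candidates: list[EnhancerCandidate], bed_path, json_path=None) -> None:
    with open(bed_path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.name}\t{c.mean_conservation:.4g}\n"
            )
    if json_path is not None:
        payload = [
            {
                "name": c.name,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "n_peaks": c.n_peaks,
                "mean_conservation": c.mean_conservation,
            }
            for c in candidates
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_peaks_bed(path) -> list[Peak]:
    from .intervals import read_bed

    return [Peak(iv, score) for iv, _, score in read_bed(path)]
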