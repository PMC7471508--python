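"""Fragment-level proximity matrices from positioned read pairs.

Each ligation product is a read pair; each mate is annotated with the
restriction fragment containing its 5' mapped position, and the symmetric
matrix of fragment-pair counts is the proximity (contact) matrix.  Raw
counts are kept — no balancing — and binning to a uniform resolution
(e.g. 20 kb) simply sums fragment counts by fragment-midpoint bin.

Pairs are consumed from a tab-separated text file with nine columns::

    readID  chrom1  pos1  strand1  chrom2  pos2  strand2  mapq1  mapq2

where positions are 1-based 5' mapped positions, as emitted by alignment
post-processing.  ``#``-prefixed header lines are allowed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .digest import FragmentMap
from .intervals import GenomicInterval

PAIRS_COLUMNS = [
    "read_id", "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2", "mapq1", "mapq2",
]

DROP_REASONS = ("low_mapq", "trans", "off_region", "same_fragment", "adjacent")


@dataclass(frozen=True)
class ContactPair:
    """One ligation read pair; positions are 1-based 5' mapped positions."""

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapq1: int
    mapq2: int


@dataclass(frozen=True)
class FilterConfig:
    """Pair-level filters applied while building the fragment matrix.

    Same-fragment pairs are self-circles/undigested products and carry no
    proximity information, so they are dropped by default.  Adjacent
    fragments are mostly religation but can carry signal; dropping them is
    optional.  Trans pairs are always excluded from the (in-cis) matrix
    but tallied.
    """

    min_mapq: int = 30
    drop_same_fragment: bool = True
    drop_adjacent_fragments: bool = False
    restrict_to_region: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class BinAxis:
    """Uniform genomic bins over a region; the last bin may be short."""

    region: GenomicInterval
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")

    @property
    def n_bins(self) -> int:
        return -(-len(self.region) // self.resolution)

    def bin_interval(self, i: int) -> GenomicInterval:
        start = self.region.start + i * self.resolution
        end = min(start + self.resolution, self.region.end)
        return GenomicInterval(self.region.chrom, start, end)

    def bin_of(self, pos: int) -> int:
        return (pos - self.region.start) // self.resolution


@dataclass
class ContactMatrix:
    """Symmetric sparse contact matrix over a fragment map or bin axis."""

    axis: FragmentMap | BinAxis
    counts: sp.csr_matrix
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def is_binned(self) -> bool:
        return isinstance(self.axis, BinAxis)

    @property
    def total(self) -> int:
        """Kept pair count: sum over the upper triangle plus the diagonal."""
        return int(sp.triu(self.counts, k=0).sum())

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def check(self) -> None:
        m = self.counts
        if m.shape[0] != m.shape[1]:
            raise ValueError("matrix not square")
        n_axis = len(self.axis) if isinstance(self.axis, FragmentMap) else self.axis.n_bins
        if m.shape[0] != n_axis:
            raise ValueError(f"matrix size {m.shape[0]} != axis size {n_axis}")
        if (m != m.T).nnz != 0:
            raise ValueError("matrix not symmetric")
        if m.data.size and m.data.min() < 0:
            raise ValueError("negative counts")


def load_pairs(path) -> Iterator[ContactPair]:
    """Stream ContactPairs from a pairs TSV, preserving order.

    Malformed lines raise a parse error naming the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(PAIRS_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(PAIRS_COLUMNS)} "
                    f"columns, got {len(parts)}"
                )
            try:
                yield ContactPair(
                    read_id=parts[0],
                    chrom1=parts[1], pos1=int(parts[2]), strand1=parts[3],
                    chrom2=parts[4], pos2=int(parts[5]), strand2=parts[6],
                    mapq1=int(parts[7]), mapq2=int(parts[8]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None


def write_pairs(path, pairs: Iterable[ContactPair]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIRS_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.read_id}\t{p.chrom1}\t{p.pos1}\t{p.strand1}"
                f"\t{p.chrom2}\t{p.pos2}\t{p.strand2}\t{p.mapq1}\t{p.mapq2}\n"
            )


def assign_pairs(
    pairs: Iterable[ContactPair], fm: FragmentMap, filters: FilterConfig | None = None
) -> ContactMatrix:
    """Build the fragment-level contact matrix from positioned pairs.

    Each mate maps to the fragment containing its 5' position (1-based in
    the file, converted to 0-based here).  Pairs failing a filter are
    tallied by the first reason that applies, in the order: low mapq,
    trans, off-region, same fragment, adjacent fragments.
    """
    if filters is None:
        filters = FilterConfig()
    tallies = {reason: 0 for reason in DROP_REASONS}
    n_input = 0
    rows: list[int] = []
    cols: list[int] = []
    chrom = fm.region.chrom
    for p in pairs:
        n_input += 1
        if p.mapq1 < filters.min_mapq or p.mapq2 < filters.min_mapq:
            tallies["low_mapq"] += 1
            continue
        if p.chrom1 != p.chrom2:
            tallies["trans"] += 1
            continue
        pos1, pos2 = p.pos1 - 1, p.pos2 - 1
        in1 = p.chrom1 == chrom and fm.region.contains(pos1)
        in2 = p.chrom2 == chrom and fm.region.contains(pos2)
        if not (in1 and in2):
            # with a single-region fragment map there is nowhere else to
            # assign a mate, so off-region pairs are tallied regardless of
            # the restrict_to_region flag
            tallies["off_region"] += 1
            continue
        i = fm.fragment_index(pos1)
        j = fm.fragment_index(pos2)
        if i == j:
            if filters.drop_same_fragment:
                tallies["same_fragment"] += 1
                continue
        elif abs(i - j) == 1 and filters.drop_adjacent_fragments:
            tallies["adjacent"] += 1
            continue
        lo, hi = min(i, j), max(i, j)
        rows.append(lo)
        cols.append(hi)
    n = len(fm)
    upper = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n, n)
    ).tocsr()
    full = upper + sp.triu(upper, k=1).T
    kept = n_input - sum(tallies.values())
    meta = {
        "level": "fragment",
        "region": str(fm.region),
        "filters": asdict(filters),
        "n_input": n_input,
        "n_kept": kept,
        "dropped": tallies,
    }
    cm = ContactMatrix(fm, full, meta)
    cm.check()
    return cm


def bin_matrix(cm: ContactMatrix, resolution: int) -> ContactMatrix:
    """Aggregate a fragment-level matrix to uniform bins.

    A fragment belongs to the bin containing its midpoint; counts are
    summed, so the matrix total is conserved exactly.
    """
    if cm.is_binned:
        raise ValueError("matrix is already binned")
    fm: FragmentMap = cm.axis
    axis = BinAxis(fm.region, min(resolution, len(fm.region)))
    mids = np.array([f.midpoint for f in fm.fragments])
    frag_bin = (mids - fm.region.start) // axis.resolution
    n_frag, n_bin = len(fm), axis.n_bins
    pool = sp.coo_matrix(
        (np.ones(n_frag), (frag_bin, np.arange(n_frag))), shape=(n_bin, n_frag)
    ).tocsr()
    # aggregate the upper-triangle representation (one entry per unordered
    # pair) so that two fragments landing in the same bin contribute one
    # count to the bin diagonal, then re-symmetrize; fragment order is
    # nondecreasing in bin index, so the pooled matrix stays upper-triangular
    upper = sp.triu(cm.counts, k=0)
    pooled = (pool @ upper @ pool.T).tocsr()
    binned = pooled + sp.triu(pooled, k=1).T
    binned.data = binned.data.astype(np.int64)
    meta = dict(cm.metadata)
    meta.update(level="binned", resolution=axis.resolution)
    out = ContactMatrix(axis, binned, meta)
    out.check()
    return out


def _axis_to_json(axis: FragmentMap | BinAxis) -> dict:
    if isinstance(axis, BinAxis):
        return {
            "kind": "bins",
            "chrom": axis.region.chrom,
            "start": axis.region.start,
            "end": axis.region.end,
            "resolution": axis.resolution,
        }
    return {
        "kind": "fragments",
        "chrom": axis.region.chrom,
        "start": axis.region.start,
        "end": axis.region.end,
        "cut_positions": axis.cut_positions,
    }


def _axis_from_json(d: dict) -> FragmentMap | BinAxis:
    region = GenomicInterval(d["chrom"], d["start"], d["end"])
    if d["kind"] == "bins":
        return BinAxis(region, d["resolution"])
    return FragmentMap(region, d["cut_positions"])


def write_matrix(cm: ContactMatrix, prefix) -> None:
    """Write a matrix as sparse upper-triangle triplets + a JSON sidecar.

    Produces ``<prefix>.triplets.tsv`` (bin_i, bin_j, count with i <= j)
    and ``<prefix>.json`` (axis + metadata).
    """
    prefix = Path(prefix)
    upper = sp.triu(cm.counts, k=0).tocoo()
    df = pd.DataFrame({"i": upper.row, "j": upper.col, "count": upper.data})
    df = df.sort_values(["i", "j"])
    df.to_csv(prefix.with_suffix(".triplets.tsv"), sep="\t", index=False)
    sidecar = {
        "n": cm.n,
        "axis": _axis_to_json(cm.axis),
        "metadata": cm.metadata,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_matrix(prefix) -> ContactMatrix:
    """Read a matrix written by :func:`write_matrix`; read∘write is identity."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    axis = _axis_from_json(sidecar["axis"])
    n = sidecar["n"]
    n_axis = len(axis) if isinstance(axis, FragmentMap) else axis.n_bins
    if n != n_axis:
        raise ValueError(f"{prefix}: sidecar n={n} inconsistent with axis size {n_axis}")
    df = pd.read_csv(prefix.with_suffix(".triplets.tsv"), sep="\t")
    if len(df) and (df["i"].max() >= n or df["j"].max() >= n or df[["i", "j"]].min().min() < 0):
        raise ValueError(f"{prefix}: triplet index outside axis (n={n})")
    if len(df) and (df["i"] > df["j"]).any():
        raise ValueError(f"{prefix}: triplets must have i <= j")
    upper = sp.coo_matrix(
        (df["count"].to_numpy(np.int64), (df["i"], df["j"])), shape=(n, n)
    ).tocsr()
    full = upper + sp.triu(upper, k=1).T
    cm = ContactMatrix(axis, full, sidecar["metadata"])
    cm.check()
    return cm


def write_dense(cm: ContactMatrix, path) -> None:
    """Dense TSV export, mainly for plotting and inspection."""
    np.savetxt(path, cm.dense(), fmt="%d", delimiter="\t")
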