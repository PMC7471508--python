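"""In-silico restriction digestion and fragment-size statistics.

A capture-based chromatin conformation experiment resolves contacts at the
level of restriction fragments, so the ordered fragment map of the capture
region is the coordinate backbone of the whole pipeline.  ApoI (R^AATTY, a
6-cutter with two degenerate positions, effectively a ~1 kb cutter on
random sequence and ~500 bp in AT-rich loci) generates that map; DpnII
(^GATC) is included because it is the other enzyme commonly used in this
family of protocols.

Matching is IUPAC-expanded on the top strand only, which is sufficient for
palindromic recognition sites; non-palindromic enzymes are rejected rather
than silently half-digested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzymeSpec:
    """A restriction enzyme: IUPAC recognition pattern and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        bad = set(rec) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        """Palindromic under IUPAC reverse complement (e.g. RAATTY, GATC)."""
        return reverse_complement(self.recognition) == self.recognition


APOI = RestrictionEnzymeSpec("ApoI", "RAATTY", 1)
DPNII = RestrictionEnzymeSpec("DpnII", "GATC", 0)

ENZYMES = {"ApoI": APOI, "DpnII": DPNII}


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling a capture region exactly."""

    region: GenomicInterval
    cut_positions: list[int]
    fragments: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fragments:
            bounds = [self.region.start]
            bounds += [self.region.start + c for c in self.cut_positions]
            bounds.append(self.region.end)
            self.fragments = [
                GenomicInterval(self.region.chrom, a, b)
                for a, b in zip(bounds[:-1], bounds[1:])
            ]
        self._starts = np.array([f.start for f in self.fragments])

    def __len__(self) -> int:
        return len(self.fragments)

    def fragment_index(self, pos: int) -> int:
        """Index of the fragment containing a 0-based genomic position.

        Raises IndexError for positions outside the region.
        """
        if not self.region.contains(pos):
            raise IndexError(f"position {pos} outside region {self.region}")
        return int(np.searchsorted(self._starts, pos, side="right")) - 1

    def fragment_indices(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized fragment_index; positions must all lie in the region."""
        return np.searchsorted(self._starts, positions, side="right") - 1

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, f in enumerate(self.fragments):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tfrag_{i}\n")

    @classmethod
    def from_bed(cls, path, region: GenomicInterval | None = None) -> "FragmentMap":
        from .intervals import read_bed

        frags = [iv for iv, _, _ in read_bed(path)]
        if not frags:
            raise ValueError(f"{path}: no fragments")
        if region is None:
            region = GenomicInterval(frags[0].chrom, frags[0].start, frags[-1].end)
        cuts = [f.start - region.start for f in frags[1:]]
        return cls(region, cuts, frags)


def _expand_pattern(pattern: str) -> list[set[str]]:
    return [set(IUPAC[sym]) for sym in pattern.upper()]


def find_cut_sites(sequence: str, enzyme: RestrictionEnzymeSpec) -> list[int]:
    """Top-strand cut positions (0-based) of an enzyme in a sequence.

    One cut per recognition match, at match_start + cut_offset.  IUPAC
    degeneracy in the pattern is expanded; N in the *sequence* never
    matches (an unknown base cannot be asserted to be a site).  Lowercase
    (soft-masked) bases match their uppercase equivalents.
    """
    if not enzyme.is_palindromic:
        raise ValueError(
            f"{enzyme.name}: non-palindromic recognition sites are not supported "
            "(top-strand-only matching would miss bottom-strand sites)"
        )
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    arr0 = np.frombuffer(seq.encode("ascii", errors="replace"), dtype="S1")
    valid = np.zeros(len(arr0), dtype=bool)
    for b in b"ACGTN":
        valid |= arr0 == bytes([b])
    if not valid.all():
        off = int(np.flatnonzero(~valid)[0])
        raise ValueError(f"invalid character {seq[off]!r} at offset {off}")
    n_frac = seq.count("N") / len(seq)
    if n_frac > 0.01:
        warnings.warn(
            f"sequence is {n_frac:.1%} N; fragments spanning N runs will be inflated",
            stacklevel=2,
        )
    pattern = _expand_pattern(enzyme.recognition)
    L = len(pattern)
    if len(seq) < L:
        return []
    # vectorized window match over a byte view of the sequence
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n_win = len(seq) - L + 1
    hit = np.ones(n_win, dtype=bool)
    for k, bases in enumerate(pattern):
        col = arr[k : k + n_win]
        ok = np.zeros(n_win, dtype=bool)
        for b in bases:
            ok |= col == b.encode()
        hit &= ok
    starts = np.flatnonzero(hit)
    return [int(s) + enzyme.cut_offset for s in starts]


def digest_region(
    sequence: str, enzyme: RestrictionEnzymeSpec, region: GenomicInterval
) -> FragmentMap:
    """Digest a region's sequence into its restriction-fragment map.

    Cuts falling exactly on the region edges are dropped (they create no
    internal boundary).
    """
    if len(sequence) != len(region):
        raise ValueError(
            f"sequence length {len(sequence)} != region length {len(region)}"
        )
    cuts = [c for c in find_cut_sites(sequence, enzyme) if 0 < c < len(region)]
    return FragmentMap(region, cuts)


def fragment_stats(fm: FragmentMap, bin_width: int = 100) -> dict:
    """Count, mean, median and a size histogram of a fragment map.

    The histogram uses ``bin_width``-bp bins from 0 to the longest fragment.
    """
    if len(fm) == 0:
        raise ValueError("empty fragment map")
    lengths = np.array([len(f) for f in fm.fragments])
    edges = np.arange(0, lengths.max() + bin_width, bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    return {
        "count": int(len(lengths)),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": int(lengths.min()),
        "max": int(lengths.max()),
        "histogram": {
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
        },
    }


def write_stats(stats: dict, json_path, tsv_path=None) -> None:
    """Serialize fragment statistics as JSON and an optional histogram TSV."""
    with open(json_path, "w") as fh:
        json.dump(stats, fh, indent=2)
    if tsv_path is not None:
        hist = stats["histogram"]
        with open(tsv_path, "w") as fh:
            fh.write("bin_start\tbin_end\tcount\n")
            for lo, hi, c in zip(
                hist["bin_edges"][:-1], hist["bin_edges"][1:], hist["counts"]
            ):
                fh.write(f"{lo}\t{hi}\t{c}\n")


def read_fasta_record(path, name: str | None = None) -> tuple[str, str]:
    """Read one record from a (multi-)FASTA; returns (name, sequence).

    If ``name`` is None the first record is returned.
    """
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return rec.id, str(rec.seq)
    raise KeyError(f"record {name!r} not found in {path}")
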