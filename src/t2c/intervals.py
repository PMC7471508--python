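"""Genomic intervals and coordinate-convention helpers.

All internal coordinates are 0-based half-open, the convention of BED and
of every array slice in this package.  Coordinates printed in genome
browsers and papers are usually 1-based inclusive (gene annotations) or
round-number bin edges that are already half-open in spirit; the parser
below converts either convention explicitly rather than guessing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

Convention = Literal["inclusive-1-based", "bin-edge-half-open"]

_COORD_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+)\s*:\s*(?P<start>[\d,]+)\s*[–—-]\s*(?P<end>[\d,]+)\s*$"
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} in {self.chrom}")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_genomic_coordinate(
    text: str, convention: Convention = "bin-edge-half-open"
) -> GenomicInterval:
    """Parse a printed ``chrom:start-end`` coordinate into an internal interval.

    ``convention`` states how the printed numbers are meant:

    * ``"bin-edge-half-open"`` — round-number map coordinates where the
      printed end is an exclusive bin edge; length = end - start.
    * ``"inclusive-1-based"`` — browser/annotation style where both
      endpoints are included; length = end - start + 1.  Internally the
      start shifts down by one base.

    Unicode en/em dashes and embedded commas are accepted.
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse genomic coordinate {text!r}")
    chrom = m.group("chrom")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start >= end:
        raise ValueError(f"start >= end in coordinate {text!r}")
    if convention == "inclusive-1-based":
        return GenomicInterval(chrom, start - 1, end)
    if convention == "bin-edge-half-open":
        return GenomicInterval(chrom, start, end)
    raise ValueError(f"unknown coordinate convention {convention!r}")


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on the same chromosome (0 if they overlap)."""
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    earlier, later = (a, b) if a.start <= b.start else (b, a)
    return max(0, later.start - earlier.end)


def read_bed(path) -> list[tuple[GenomicInterval, str, float | None]]:
    """Read a BED3+ file; returns (interval, name, score) per record.

    Missing name column yields "", missing score yields None.  Track and
    comment lines are skipped.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            records.append((iv, name, score))
    return records


def write_bed(path, records) -> None:
    """Write (interval, name, score) records as BED; name/score may be omitted."""
    with open(path, "w") as fh:
        for rec in records:
            iv, name, score = (rec + (None,) * 3)[:3] if isinstance(rec, tuple) else (rec, "", None)
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name or score is not None:
                cols.append(name or ".")
            if score is not None:
                cols.append(f"{score:g}")
            fh.write("\t".join(cols) + "\n")
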