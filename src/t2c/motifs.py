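"""PWM motif scanning of enhancer sequences.

Profiles are position frequency matrices in JASPAR text format.  Counts
are converted to log2 odds against a background (uniform by default)
after adding a pseudocount split proportionally to the background, and
every window of a sequence is scored on both strands.  Scores are
reported on the relative scale

    relative = (score - min_score) / (max_score - min_score)

where min/max are the sums of per-column minima/maxima of the log-odds
matrix, so 1.0 is the best attainable match and the conventional
"confidence > 90%" cutoff is ``threshold = 0.90``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .digest import read_fasta_record, reverse_complement
from .regulatory import EnhancerCandidate

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """A position frequency matrix with scoring parameters.

    counts is a 4 x L array in row order A, C, G, T.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.name}: counts must be 4 x L")
        if (self.counts < 0).any():
            raise ValueError(f"{self.name}: negative counts")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"{self.name}: background must sum to 1")
        if ((self.counts.sum(axis=0) + self.pseudocount) <= 0).any():
            raise ValueError(f"{self.name}: non-positive column total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix with background-split pseudocounts."""
        totals = self.counts.sum(axis=0) + self.pseudocount
        probs = (self.counts + self.pseudocount * self.background[:, None]) / totals
        return np.log2(probs / self.background[:, None])

    def score_range(self) -> tuple[float, float]:
        lom = self.log_odds()
        return float(lom.min(axis=0).sum()), float(lom.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """One PWM match on a scanned sequence."""

    sequence_name: str
    motif_name: str
    offset: int  # 0-based window start on the forward strand
    strand: str  # "+" or "-"
    score: float  # log2-odds
    relative: float  # in [0, 1]


def read_jaspar(text_or_path) -> list[PWM]:
    """Parse JASPAR PFM text (``>ID NAME`` header + A/C/G/T count rows).

    Accepts a path or raw text.  Malformed records raise a parse error
    naming the record.
    """
    from Bio import motifs as bio_motifs

    if "\n" in str(text_or_path) or str(text_or_path).startswith(">"):
        text = str(text_or_path)
    else:
        with open(text_or_path) as fh:
            text = fh.read()
    # drop comment lines and anything before the first record header
    text = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    first = text.find(">")
    if first < 0:
        raise ValueError("no JASPAR records found")
    text = text[first:]
    pwms: list[PWM] = []
    records = ["> " + chunk for chunk in text.split(">") if chunk.strip()]
    records = [r.replace("> ", ">", 1) for r in records]
    for rec in records:
        header = rec.splitlines()[0].lstrip(">").strip()
        try:
            parsed = bio_motifs.parse(io.StringIO(rec), "jaspar")
        except Exception as exc:
            raise ValueError(f"malformed JASPAR record {header!r}: {exc}") from None
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
            name = m.name or m.matrix_id
            pwms.append(PWM(str(name), counts))
    return pwms


def write_jaspar(pwms: list[PWM], path) -> None:
    """Write PWMs in JASPAR PFM format (integer-valued counts stay integral)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name} {p.name}\n")
            for b, row in zip(_BASES, p.counts):
                cells = " ".join(
                    f"{v:g}" for v in row
                )
                fh.write(f"{b} [ {cells} ]\n")


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to indices 0..3, with 4 for N/unknown."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype="S1") == b.encode()] = i
    return out


def scan(
    sequence: str,
    pwm: PWM,
    threshold: float = 0.90,
    sequence_name: str = "seq",
) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM matches above a relative score.

    The minus strand is scanned by scoring the reverse complement of each
    window against the PWM; the reported offset is always the window start
    on the forward strand.  Windows containing N are skipped.  When the
    PWM is fully degenerate (max score == min score) every window scores
    relative 1.0 by convention.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    L = pwm.length
    seq = sequence.upper()
    if len(seq) < L:
        warnings.warn(
            f"sequence {sequence_name!r} shorter than motif {pwm.name} ({L} bp)",
            stacklevel=2,
        )
        return []
    lom = pwm.log_odds()
    lo, hi = pwm.score_range()
    span = hi - lo
    enc_fwd = _encode(seq)
    enc_rev = _encode(reverse_complement(seq))
    n_win = len(seq) - L + 1
    # pad the log-odds matrix with a row for N so indexing is safe; those
    # windows are masked out below
    lom_pad = np.vstack([lom, np.zeros((1, L))])
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    hits: list[MotifHit] = []
    for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
        windows = enc[idx]
        valid = (windows != 4).all(axis=1)
        scores = lom_pad[windows, np.arange(L)[None, :]].sum(axis=1)
        rel = np.ones(n_win) if span == 0 else (scores - lo) / span
        for k in np.flatnonzero(valid & (rel >= threshold)):
            offset = int(k) if strand == "+" else len(seq) - L - int(k)
            hits.append(
                MotifHit(
                    sequence_name, pwm.name, offset, strand,
                    float(scores[k]), float(rel[k]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand, h.motif_name))
    return hits


def annotate_enhancers(
    candidates: list[EnhancerCandidate],
    fasta_path,
    pwms: list[PWM],
    threshold: float = 0.90,
    record_name: str | None = None,
    region_offset: int = 0,
) -> list[MotifHit]:
    """Scan every enhancer candidate's sequence with every PWM.

    ``region_offset`` is the genomic start of the FASTA record, so that
    candidate intervals (genomic) can be sliced out of it.  Hit offsets
    are relative to each candidate's start.  Results are ordered by
    (candidate, motif, offset, strand).
    """
    _, seq = read_fasta_record(fasta_path, record_name)
    hits: list[MotifHit] = []
    for cand in candidates:
        lo = cand.interval.start - region_offset
        hi = cand.interval.end - region_offset
        if lo < 0 or hi > len(seq):
            raise ValueError(
                f"candidate {cand.name} ({cand.interval}) outside FASTA record"
            )
        sub = seq[lo:hi]
        for pwm in pwms:
            hits.extend(scan(sub, pwm, threshold, sequence_name=cand.name))
    hits.sort(key=lambda h: (h.sequence_name, h.motif_name, h.offset, h.strand))
    return hits


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tmotif\toffset\tstrand\tscore\trelative\n")
        for h in hits:
            fh.write(
                f"{h.sequence_name}\t{h.motif_name}\t{h.offset}\t{h.strand}"
                f"\t{h.score:.4f}\t{h.relative:.4f}\n"
            )
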