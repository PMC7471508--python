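"""Naive reference implementations used as independent oracles in tests.

Everything here is deliberately brute-force — per-position loops, per-base
sums — and shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_cut_sites(sequence: str, pattern: str, cut_offset: int) -> list[int]:
    """Position-by-position IUPAC pattern scan; N in the sequence never matches."""
    seq = sequence.upper()
    hits = []
    for start in range(len(seq) - len(pattern) + 1):
        ok = True
        for k, sym in enumerate(pattern):
            base = seq[start + k]
            if base == "N" or base not in IUPAC[sym]:
                ok = False
                break
        if ok:
            hits.append(start + cut_offset)
    return hits


def naive_insulation(matrix: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Double-loop insulation square means; returns (raw, defined)."""
    n = matrix.shape[0]
    raw = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        if i - w + 1 < 0 or i + w > n - 1:
            continue
        total = 0.0
        for a in range(i - w + 1, i + 1):
            for b in range(i + 1, i + w + 1):
                total += matrix[a, b]
        raw[i] = total / (w * w)
        defined[i] = True
    return raw, defined


def naive_pwm_scan(sequence: str, counts: np.ndarray, pseudocount: float,
                   background: np.ndarray, threshold: float) -> list[tuple]:
    """All-windows, both-strand PWM scorer; returns (offset, strand, score, rel)."""
    bases = "ACGT"
    L = counts.shape[1]
    lom = np.zeros((4, L))
    for j in range(L):
        total = counts[:, j].sum() + pseudocount
        for b in range(4):
            p = (counts[b, j] + pseudocount * background[b]) / total
            lom[b, j] = np.log2(p / background[b])
    lo = sum(lom[:, j].min() for j in range(L))
    hi = sum(lom[:, j].max() for j in range(L))
    seq = sequence.upper()
    out = []
    for offset in range(len(seq) - L + 1):
        window = seq[offset : offset + L]
        if "N" in window:
            continue
        for strand in "+-":
            win = window if strand == "+" else "".join(
                COMPLEMENT[c] for c in reversed(window)
            )
            score = sum(lom[bases.index(win[j]), j] for j in range(L))
            rel = 1.0 if hi == lo else (score - lo) / (hi - lo)
            if rel >= threshold:
                out.append((offset, strand, score, rel))
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def naive_merge(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Repeated pairwise merging until fixpoint."""
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        for a in range(len(ivs)):
            for b in range(len(ivs)):
                if a == b:
                    continue
                (s1, e1), (s2, e2) = ivs[a], ivs[b]
                if max(s1, s2) - min(e1, e2) <= gap:
                    merged = (min(s1, s2), max(e1, e2))
                    ivs = [v for k, v in enumerate(ivs) if k not in (a, b)] + [merged]
                    ivs.sort()
                    changed = True
                    break
            if changed:
                break
    return ivs


def naive_mean_conservation(start: int, end: int, steps: list[tuple[int, int, float]]) -> float:
    """Per-base sum over the interval; uncovered bases contribute 0."""
    per_base = np.zeros(end - start)
    for s, e, v in steps:
        for pos in range(max(s, start), min(e, end)):
            per_base[pos - start] = v
    return float(per_base.mean())


def random_dna(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    alphabet = "ACGTN" if n_prob > 0 else "ACGT"
    p = None
    if n_prob > 0:
        p = [(1 - n_prob) / 4] * 4 + [n_prob]
    return "".join(rng.choice(list(alphabet), size=length, p=p))
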