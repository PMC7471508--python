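"""Synthetic capture-region experiments with planted ground truth.

Every stage of the pipeline is verifiable against a simulation that
plants the structures the real assay observes:

* a genome whose restriction-site spacing gives a chosen mean fragment
  size (sites are planted at exponential spacing on top of the background
  occurrences expected in random sequence);
* ligation pairs drawn from a bin-level contact model — power-law
  distance decay, a within-TAD enrichment, and focal loop pixels;
* one H3K27ac-like peak and a conservation plateau per planted enhancer,
  with a TF-motif consensus written into each enhancer's sequence.

The model puts zero probability on bin separations d <= 1, mirroring the
domain caller's exclusion of self/adjacent-ligation-dominated pixels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .contacts import BinAxis, ContactMatrix, ContactPair, write_pairs
from .digest import APOI, FragmentMap, digest_region
from .intervals import GenomicInterval
from .motifs import PWM, read_jaspar
from .regulatory import ConservationTrack, Peak

# expected ApoI site rate in uniform random sequence: 4 of 4096 hexamers
# match RAATTY, i.e. one site per 1024 bp
_BACKGROUND_SITE_SPACING = 1024.0

CONSERVATION_BASELINE = 0.1
CONSERVATION_ENHANCER = 1.0


@dataclass
class SimulationSpec:
    """Full description of one synthetic capture experiment."""

    chrom: str = "chr2sim"
    region_length: int = 2_000_000
    target_fragment_size: int = 500
    resolution: int = 20_000
    tad_boundaries: list[int] = field(default_factory=lambda: [33, 66])
    alpha: float = 1.0  # distance-decay exponent
    tau: float = 1.0  # within-TAD log-enrichment: exp(tau) ~ 2.7x
    loops: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(40, 65, 8.0)]
    )
    enhancers: list[tuple[int, int, str]] = field(
        default_factory=lambda: [
            (1_304_000, 1_305_000, "SOX10"),
            (1_309_500, 1_310_200, "ETS1"),
            (1_316_000, 1_316_300, "HOXB2"),
        ]
    )
    n_pairs: int = 100_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.target_fragment_size < 50:
            raise ValueError("target mean fragment size must be >= 50 bp")
        n = self.n_bins
        if sorted(self.tad_boundaries) != list(self.tad_boundaries):
            raise ValueError("TAD boundaries must be sorted")
        if any(not 0 <= b < n - 1 for b in self.tad_boundaries):
            raise ValueError("TAD boundary bin outside region")
        self.loops = [tuple(l) for l in self.loops]
        for i, j, g in self.loops:
            if not (0 <= i < j < n):
                raise ValueError(f"loop bins ({i}, {j}) invalid for {n} bins")
            if g < 1:
                raise ValueError("loop enrichment must be >= 1")
        self.enhancers = [tuple(e) for e in self.enhancers]
        for s, e, _ in self.enhancers:
            if not (0 <= s < e <= self.region_length):
                raise ValueError(f"enhancer ({s}, {e}) outside region")

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, 0, self.region_length)

    @property
    def n_bins(self) -> int:
        return -(-self.region_length // self.resolution)

    @property
    def axis(self) -> BinAxis:
        return BinAxis(self.region, self.resolution)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["loops"] = [list(l) for l in d["loops"]]
        d["enhancers"] = [list(e) for e in d["enhancers"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)


def toy_pwms() -> list[PWM]:
    """The toy TF profiles shipped with the package (synthetic stand-ins)."""
    with resources.files("t2c.data").joinpath("toy_motifs.pfm").open() as fh:
        return read_jaspar(fh.read())


def toy_pwm_path() -> Path:
    return Path(str(resources.files("t2c.data").joinpath("toy_motifs.pfm")))


_APOI_SITES = ["AAATTC", "AAATTT", "GAATTC", "GAATTT"]


def make_genome(spec: SimulationSpec) -> tuple[str, FragmentMap]:
    """Generate the region's sequence and its true ApoI fragment map.

    Bases are i.i.d. uniform; concrete RAATTY realisations are planted at
    exponential spacing whose rate tops up the background occurrence rate
    (one per ~1024 bp in uniform sequence) to hit the target mean fragment
    size.  Background sites arising by chance stay in the map.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.region_length
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)
    extra_rate = max(1.0 / spec.target_fragment_size - 1.0 / _BACKGROUND_SITE_SPACING, 0.0)
    if extra_rate > 0:
        pos = 0.0
        while True:
            pos += rng.exponential(1.0 / extra_rate)
            start = int(pos)
            if start + 6 > n:
                break
            site = _APOI_SITES[rng.integers(len(_APOI_SITES))]
            seq[start : start + 6] = np.frombuffer(site.encode(), dtype="S1")
    sequence = seq.tobytes().decode("ascii")
    return sequence, digest_region(sequence, APOI, spec.region)


def _tad_ids(spec: SimulationSpec) -> np.ndarray:
    """TAD membership per bin; boundary bin b separates bins <= b from > b."""
    return np.searchsorted(spec.tad_boundaries, np.arange(spec.n_bins), side="left")


def contact_probabilities(spec: SimulationSpec) -> np.ndarray:
    """Upper-triangle contact probabilities of the planted model.

    w(i, j) = (|i-j| + 1)^(-alpha) * exp(tau * [same TAD]) * gamma_loop
    for |i-j| >= 2, zero otherwise; normalised to sum 1 over i < j.
    Returned as a dense n x n array with the lower triangle zero.
    """
    n = spec.n_bins
    i, j = np.triu_indices(n, k=2)
    d = j - i
    w = (d + 1.0) ** (-spec.alpha)
    tads = _tad_ids(spec)
    w *= np.exp(spec.tau * (tads[i] == tads[j]))
    probs = np.zeros((n, n))
    probs[i, j] = w
    for li, lj, gamma in spec.loops:
        if lj - li >= 2:
            probs[li, lj] *= gamma
    probs /= probs.sum()
    return probs


def truth_matrix(spec: SimulationSpec) -> ContactMatrix:
    """The binned truth matrix alone, without placing reads in fragments.

    Uses the same random stream as :func:`simulate_pairs` (the multinomial
    draw is its first use), so for a given spec the two agree exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_bins
    probs = contact_probabilities(spec)
    iu, ju = np.triu_indices(n, k=2)
    draws = rng.multinomial(spec.n_pairs, probs[iu, ju])
    truth = np.zeros((n, n), dtype=np.int64)
    np.add.at(truth, (iu, ju), draws)
    truth = truth + truth.T
    import scipy.sparse as sp

    cm = ContactMatrix(
        spec.axis,
        sp.csr_matrix(truth),
        {
            "level": "binned",
            "resolution": spec.resolution,
            "region": str(spec.region),
            "source": "simulation truth",
            "n_input": spec.n_pairs,
            "n_kept": spec.n_pairs,
        },
    )
    cm.check()
    return cm


def simulate_pairs(
    spec: SimulationSpec, sequence: str, fm: FragmentMap
) -> tuple[list[ContactPair], ContactMatrix]:
    """Draw ligation pairs from the planted model.

    Returns the pairs and the true binned matrix (the multinomial draw
    itself), which the contacts module reproduces exactly from the pairs:
    each endpoint is placed in a uniformly chosen fragment whose midpoint
    falls in the target bin, at a uniform position inside the fragment.
    """
    if spec.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    axis = spec.axis
    n = spec.n_bins
    probs = contact_probabilities(spec)
    iu, ju = np.triu_indices(n, k=2)
    draws = rng.multinomial(spec.n_pairs, probs[iu, ju])
    # fragments ordered by start => midpoint bins are nondecreasing, so the
    # fragments of each bin form a contiguous index range
    mids = np.array([f.midpoint for f in fm.fragments])
    frag_bin = mids // axis.resolution
    first = np.searchsorted(frag_bin, np.arange(n), side="left")
    count = np.searchsorted(frag_bin, np.arange(n), side="right") - first
    needed = np.zeros(n, dtype=np.int64)
    np.add.at(needed, iu, draws)
    np.add.at(needed, ju, draws)
    if ((count == 0) & (needed > 0)).any():
        b = int(np.flatnonzero((count == 0) & (needed > 0))[0])
        raise RuntimeError(f"bin {b} has contacts but no fragment midpoint")
    truth = np.zeros((n, n), dtype=np.int64)
    np.add.at(truth, (iu, ju), draws)
    truth = truth + truth.T

    bi = np.repeat(iu, draws)
    bj = np.repeat(ju, draws)
    starts = np.array([f.start for f in fm.fragments])
    lens = np.array([len(f) for f in fm.fragments])

    def place(bins: np.ndarray) -> np.ndarray:
        fid = first[bins] + (rng.random(bins.size) * count[bins]).astype(np.int64)
        return starts[fid] + (rng.random(bins.size) * lens[fid]).astype(np.int64) + 1

    pos1, pos2 = place(bi), place(bj)  # 1-based 5' positions
    strands = np.array(["+", "-"])
    s1 = strands[rng.integers(2, size=bi.size)]
    s2 = strands[rng.integers(2, size=bi.size)]
    pairs = [
        ContactPair(f"read{r}", spec.chrom, int(p1), str(x1), spec.chrom, int(p2), str(x2), 60, 60)
        for r, (p1, x1, p2, x2) in enumerate(zip(pos1, s1, pos2, s2))
    ]
    import scipy.sparse as sp

    cm = ContactMatrix(
        axis,
        sp.csr_matrix(truth),
        {
            "level": "binned",
            "resolution": axis.resolution,
            "region": str(spec.region),
            "source": "simulation truth",
            "n_input": spec.n_pairs,
            "n_kept": spec.n_pairs,
        },
    )
    cm.check()
    return pairs, cm


def distal_anchors(spec: SimulationSpec) -> list[GenomicInterval]:
    """Genomic intervals of each loop's distal (right) anchor bin."""
    return [spec.axis.bin_interval(j) for _, j, _ in spec.loops]


def plant_tracks(
    spec: SimulationSpec, sequence: str
) -> tuple[str, list[Peak], ConservationTrack, dict]:
    """Plant peaks, conservation and motif consensus sequences for enhancers.

    Each planted enhancer gets one peak over its interval, conservation
    raised to 1.0 (baseline 0.1 elsewhere), and the consensus of its named
    toy profile written into the centre of its sequence.  Returns the
    edited sequence, the peak list, the conservation track and a truth
    record of everything planted.

    Enhancers must fall inside the distal anchor bin of a planted loop.
    """
    anchors = distal_anchors(spec)
    pwm_by_name = {p.name: p for p in toy_pwms()}
    seq = list(sequence)
    peaks: list[Peak] = []
    steps: list[tuple[int, int, float]] = []
    truth_enh = []
    cursor = 0
    for k, (s, e, motif_name) in enumerate(sorted(spec.enhancers), start=1):
        iv = GenomicInterval(spec.chrom, s, e)
        if e > spec.region_length:
            raise ValueError(f"enhancer {iv} outside region")
        if not any(a.start <= s and e <= a.end for a in anchors):
            raise ValueError(f"enhancer {iv} not inside any distal loop anchor")
        if motif_name not in pwm_by_name:
            raise KeyError(f"unknown toy motif {motif_name!r}")
        consensus = pwm_by_name[motif_name].consensus()
        offset = s + (e - s - len(consensus)) // 2
        seq[offset : offset + len(consensus)] = list(consensus)
        peaks.append(Peak(iv, 10.0))
        if s > cursor:
            steps.append((cursor, s, CONSERVATION_BASELINE))
        steps.append((s, e, CONSERVATION_ENHANCER))
        cursor = e
        truth_enh.append(
            {
                "name": f"Enh{k}",
                "start": s,
                "end": e,
                "motif": motif_name,
                "motif_offset": offset - s,
                "consensus": consensus,
            }
        )
    if cursor < spec.region_length:
        steps.append((cursor, spec.region_length, CONSERVATION_BASELINE))
    cons = ConservationTrack(
        [GenomicInterval(spec.chrom, a, b) for a, b, _ in steps],
        [v for _, _, v in steps],
    )
    truth = {
        "enhancers": truth_enh,
        "tad_boundaries": list(spec.tad_boundaries),
        "loops": [list(l) for l in spec.loops],
        "anchors": [[a.start, a.end] for a in anchors],
    }
    return "".join(seq), peaks, cons, truth


def simulate(spec: SimulationSpec, out_dir) -> dict:
    """Run the full generator and write every pipeline input to ``out_dir``.

    Emits: genome FASTA, truth fragment BED, pairs TSV, truth binned
    matrix, peaks BED, conservation bedGraph, the toy PFM path, the spec
    YAML and a truth JSON.  Returns a manifest of the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequence, _ = make_genome(spec)
    sequence, peaks, cons, truth = plant_tracks(spec, sequence)
    # motif planting edits the sequence, so the final fragment map is the
    # digest of the emitted sequence
    fm = digest_region(sequence, APOI, spec.region)
    pairs, truth_cm = simulate_pairs(spec, sequence, fm)

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{spec.chrom}\n")
        for k in range(0, len(sequence), 80):
            fh.write(sequence[k : k + 80] + "\n")
    fm.to_bed(out / "fragments.bed")
    write_pairs(out / "pairs.tsv", pairs)
    from .contacts import write_matrix

    write_matrix(truth_cm, out / "truth_matrix")
    with open(out / "peaks.bed", "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\tpeak\t{p.signal:g}\n"
            )
    cons.to_bedgraph(out / "conservation.bedgraph")
    spec.to_yaml(out / "simulation.yaml")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "fasta": str(fasta),
        "fragments": str(out / "fragments.bed"),
        "pairs": str(out / "pairs.tsv"),
        "truth_matrix": str(out / "truth_matrix"),
        "peaks": str(out / "peaks.bed"),
        "conservation": str(out / "conservation.bedgraph"),
        "pfm": str(toy_pwm_path()),
        "spec": str(out / "simulation.yaml"),
        "truth": str(out / "truth.json"),
    }
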