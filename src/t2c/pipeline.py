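"""End-to-end orchestration: one config, ordered stages, a run manifest.

Stages run in the order digest -> contacts -> bin -> domains/loops ->
enhancers -> motifs.  Every parameter actually used is recorded in the
manifest, together with a sha256 checksum per output file, so a rerun
with the same config and inputs is byte-identical and verifiable.  When a
previous manifest exists with the same config hash and all of a stage's
outputs are present, the stage is resumed from disk instead of recomputed
(unless ``force``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .contacts import (
    FilterConfig,
    assign_pairs,
    bin_matrix,
    load_pairs,
    read_matrix,
    write_matrix,
)
from .digest import ENZYMES, FragmentMap, digest_region, fragment_stats, read_fasta_record, write_stats
from .domains import (
    call_boundaries,
    call_loops,
    insulation_profile,
    write_boundaries_bed,
    write_loops_bedpe,
)
from .intervals import GenomicInterval, parse_genomic_coordinate
from .motifs import annotate_enhancers, read_jaspar, write_hits_tsv
from .regulatory import (
    ConservationTrack,
    call_enhancer_candidates,
    read_peaks_bed,
    write_candidates,
)

log = logging.getLogger("t2c")


@dataclass
class RunConfig:
    """All inputs, outputs and stage parameters of one pipeline run."""

    # inputs
    fasta: str = ""
    fasta_record: str | None = None
    region: str = ""  # "chrom:start-end", half-open bin edges
    pairs: str = ""
    peaks: str = ""
    conservation: str = ""
    pfm: str = ""
    out_dir: str = "t2c_run"
    # digest
    enzyme: str = "ApoI"
    # contacts
    min_mapq: int = 30
    drop_same_fragment: bool = True
    drop_adjacent_fragments: bool = False
    restrict_to_region: bool = True
    resolution: int = 20_000
    # domains
    window: int = 5
    delta: float = 0.5
    loop_min_separation: int = 3
    loop_enrichment: float = 3.0
    loop_min_count: float = 5.0
    # enhancers; empty anchor means "distal anchor of the strongest loop"
    anchor: str = ""
    merge_gap: int = 2000
    min_cons: float = 0.0
    # motifs
    motif_threshold: float = 0.90
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_all(config: RunConfig, force: bool = False) -> dict:
    """Execute the pipeline and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("fasta", "pairs", "peaks", "conservation", "pfm"):
        p = getattr(config, key)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"input {key!r} not found: {p}")
    if config.enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {config.enzyme!r} (have {sorted(ENZYMES)})")

    cfg_hash = config.config_hash()
    prev_manifest = None
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        try:
            with open(manifest_path) as fh:
                prev = json.load(fh)
            if prev.get("config_hash") == cfg_hash:
                prev_manifest = prev
        except (json.JSONDecodeError, OSError):
            prev_manifest = None

    def resumable(*paths) -> bool:
        return prev_manifest is not None and all(Path(p).exists() for p in paths)

    manifest: dict = {
        "t2c_version": __version__,
        "config_hash": cfg_hash,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    region = parse_genomic_coordinate(config.region, "bin-edge-half-open")

    # ---- digest -----------------------------------------------------
    frag_bed = out / "fragments.bed"
    stats_json = out / "fragment_stats.json"
    try:
        if resumable(frag_bed, stats_json):
            log.info("digest: resuming from %s", frag_bed)
            fm = FragmentMap.from_bed(frag_bed, region)
            with open(stats_json) as fh:
                stats = json.load(fh)
        else:
            name, seq = read_fasta_record(config.fasta, config.fasta_record)
            if len(seq) != len(region):
                raise ValueError(
                    f"FASTA record {name!r} length {len(seq)} != region {region}"
                )
            fm = digest_region(seq, ENZYMES[config.enzyme], region)
            stats = fragment_stats(fm)
            fm.to_bed(frag_bed)
            write_stats(stats, stats_json, out / "fragment_stats.tsv")
    except Exception as exc:
        raise StageError("digest", str(exc)) from exc
    manifest["stages"]["digest"] = {
        "enzyme": config.enzyme,
        "n_fragments": len(fm),
        "mean_fragment_size": stats["mean"],
        "outputs": [str(frag_bed), str(stats_json)],
    }
    log.info("digest: %d fragments, mean %.1f bp", len(fm), stats["mean"])

    # ---- contacts ---------------------------------------------------
    frag_prefix = out / "matrix_fragment"
    filters = FilterConfig(
        min_mapq=config.min_mapq,
        drop_same_fragment=config.drop_same_fragment,
        drop_adjacent_fragments=config.drop_adjacent_fragments,
        restrict_to_region=config.restrict_to_region,
    )
    try:
        if resumable(frag_prefix.with_suffix(".triplets.tsv"), frag_prefix.with_suffix(".json")):
            log.info("contacts: resuming from %s", frag_prefix)
            cm = read_matrix(frag_prefix)
        else:
            cm = assign_pairs(load_pairs(config.pairs), fm, filters)
            write_matrix(cm, frag_prefix)
    except Exception as exc:
        raise StageError("contacts", str(exc)) from exc
    manifest["stages"]["contacts"] = {
        "filters": dataclasses.asdict(filters),
        "n_input": cm.metadata.get("n_input"),
        "n_kept": cm.metadata.get("n_kept"),
        "dropped": cm.metadata.get("dropped"),
        "outputs": [str(frag_prefix) + ".triplets.tsv", str(frag_prefix) + ".json"],
    }

    # ---- bin --------------------------------------------------------
    bin_prefix = out / f"matrix_bin{config.resolution}"
    try:
        if resumable(bin_prefix.with_suffix(".triplets.tsv"), bin_prefix.with_suffix(".json")):
            bm = read_matrix(bin_prefix)
        else:
            bm = bin_matrix(cm, config.resolution)
            write_matrix(bm, bin_prefix)
    except Exception as exc:
        raise StageError("bin", str(exc)) from exc
    manifest["stages"]["bin"] = {
        "resolution": config.resolution,
        "n_bins": bm.n,
        "total": bm.total,
        "outputs": [str(bin_prefix) + ".triplets.tsv", str(bin_prefix) + ".json"],
    }

    # ---- domains + loops -------------------------------------------
    ins_path = out / "insulation.bedgraph"
    bnd_path = out / "boundaries.bed"
    loop_path = out / "loops.bedpe"
    try:
        profile = insulation_profile(bm, config.window)
        boundaries = call_boundaries(profile, config.delta)
        loops = call_loops(
            bm,
            min_separation_bins=config.loop_min_separation,
            enrichment_threshold=config.loop_enrichment,
            min_count=config.loop_min_count,
        )
        profile.to_bedgraph(ins_path)
        write_boundaries_bed(boundaries, bm.axis, bnd_path)
        write_loops_bedpe(loops, loop_path)
    except Exception as exc:
        raise StageError("domains", str(exc)) from exc
    manifest["stages"]["domains"] = {
        "window": config.window,
        "delta": config.delta,
        "boundaries": [b.bin_index for b in boundaries],
        "n_loops": len(loops),
        "loops": [
            {
                "bin_i": l.bin_i,
                "bin_j": l.bin_j,
                "span": l.span,
                "enrichment": round(l.enrichment, 3),
            }
            for l in loops
        ],
        "outputs": [str(ins_path), str(bnd_path), str(loop_path)],
    }
    log.info("domains: %d boundaries, %d loops", len(boundaries), len(loops))

    # ---- enhancers --------------------------------------------------
    enh_bed = out / "enhancers.bed"
    enh_json = out / "enhancers.json"
    try:
        if config.anchor:
            anchor = parse_genomic_coordinate(config.anchor, "bin-edge-half-open")
        else:
            if not loops:
                raise ValueError("no loops called and no anchor configured")
            best = max(loops, key=lambda l: l.enrichment)
            anchor = best.anchor_j
        peaks = read_peaks_bed(config.peaks)
        cons = ConservationTrack.from_bedgraph(config.conservation)
        candidates = call_enhancer_candidates(
            anchor, peaks, cons, merge_gap=config.merge_gap, min_cons=config.min_cons
        )
        write_candidates(candidates, enh_bed, enh_json)
    except Exception as exc:
        raise StageError("enhancers", str(exc)) from exc
    manifest["stages"]["enhancers"] = {
        "anchor": str(anchor),
        "merge_gap": config.merge_gap,
        "min_cons": config.min_cons,
        "n_candidates": len(candidates),
        "candidates": [
            {"name": c.name, "interval": str(c.interval), "n_peaks": c.n_peaks}
            for c in candidates
        ],
        "outputs": [str(enh_bed), str(enh_json)],
    }
    log.info("enhancers: %d candidates in %s", len(candidates), anchor)

    # ---- motifs -----------------------------------------------------
    hits_path = out / "motif_hits.tsv"
    try:
        pwms = read_jaspar(config.pfm)
        hits = annotate_enhancers(
            candidates,
            config.fasta,
            pwms,
            threshold=config.motif_threshold,
            record_name=config.fasta_record,
            region_offset=region.start,
        )
        write_hits_tsv(hits, hits_path)
    except Exception as exc:
        raise StageError("motifs", str(exc)) from exc
    manifest["stages"]["motifs"] = {
        "threshold": config.motif_threshold,
        "n_hits": len(hits),
        "outputs": [str(hits_path)],
    }

    checksums = {}
    for stage in manifest["stages"].values():
        for p in stage["outputs"]:
            checksums[p] = _sha256(p)
    manifest["checksums"] = checksums
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
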