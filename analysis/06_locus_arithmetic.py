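#!/usr/bin/env python
"""Recompute the published coordinate arithmetic of the ZEB2 locus.

Works from printed coordinates only: the capture-region span, the loop
anchor separation, the promoter-side region length, the enhancer-cluster
count in the distal region, and the enhancer-to-TSS distance.
"""

import argparse
import json
from pathlib import Path

from t2c.intervals import GenomicInterval, interval_distance, parse_genomic_coordinate
from t2c.regulatory import Peak, call_enhancer_candidates

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/locus_arithmetic.json"))
args = parser.parse_args()

capture = parse_genomic_coordinate("chr2:143270465-150642631", "inclusive-1-based")
print(f"capture region: {len(capture):,} bp = {len(capture)/1e6:.1f} Mb")

a = parse_genomic_coordinate("chr2:145305000-145310000")
b = parse_genomic_coordinate("chr2:145600000-145605000")
print(f"loop anchor span (start-to-start): {(b.start - a.start)/1000:.0f} kb")

region_a = parse_genomic_coordinate("chr2:145260000-145280000")
region_b = parse_genomic_coordinate("chr2:145760000-145780000")
print(f"region A (promoter side): {len(region_a)/1000:.0f} kb")

gene = parse_genomic_coordinate("chr2:145141942-145277958", "inclusive-1-based")
tss_side = GenomicInterval("chr2", gene.end - 1, gene.end)  # ZEB2 is minus-strand
gap = interval_distance(tss_side, region_b)
print(f"TSS to distal region B: {gap:,} bp ~ {round(gap/100_000)*100} kb upstream")

printed_clusters = [
    (145_764_483, 145_765_504),
    (145_769_677, 145_770_210),
    (145_779_965, 145_780_193),
]
candidates = call_enhancer_candidates(
    region_b, [Peak(GenomicInterval("chr2", s, e)) for s, e in printed_clusters],
    merge_gap=2000,
)
print(f"{len(candidates)} enhancer candidates in region B: "
      + ", ".join(f"{c.name}={c.interval}" for c in candidates))

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps({
    "capture_region_bp": len(capture),
    "capture_region_mb": round(len(capture) / 1e6, 1),
    "loop_span_bp": b.start - a.start,
    "region_a_bp": len(region_a),
    "tss_to_region_b_bp": gap,
    "n_enhancer_candidates": len(candidates),
    "candidates": [
        {"name": c.name, "start": c.interval.start, "end": c.interval.end}
        for c in candidates
    ],
}, indent=2))
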