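#!/usr/bin/env python
"""Call TAD boundaries and loops on the binned map; compare to planted truth.

Insulation-score minima (5-bin window, depth 0.5) give the boundaries; the
loop caller flags pixels enriched >= 3x over distance-decay expectation and
over their local neighbourhood.  The planted loop should be the top call and
both planted boundaries should be recovered within one bin.
"""

import argparse
from pathlib import Path

from t2c.contacts import read_matrix
from t2c.domains import (
    call_boundaries,
    call_loops,
    insulation_profile,
    write_boundaries_bed,
    write_loops_bedpe,
)
from t2c.synthetic import SimulationSpec

parser = argparse.ArgumentParser()
parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
parser.add_argument("--resolution", type=int, default=20_000)
args = parser.parse_args()

spec = SimulationSpec.from_yaml(args.sim_dir / "simulation.yaml")
bm = read_matrix(args.out_dir / f"matrix_bin{args.resolution}")

profile = insulation_profile(bm, 5)
boundaries = call_boundaries(profile, 0.5)
loops = call_loops(bm)

profile.to_bedgraph(args.out_dir / "insulation.bedgraph")
write_boundaries_bed(boundaries, bm.axis, args.out_dir / "boundaries.bed")
write_loops_bedpe(loops, args.out_dir / "loops.bedpe")

called = [b.bin_index for b in boundaries]
print(f"boundaries at bins {called} (planted: {spec.tad_boundaries})")
for planted in spec.tad_boundaries:
    hit = min((abs(b - planted) for b in called), default=None)
    print(f"  planted boundary {planted}: recovered within {hit} bin(s)")

top = max(loops, key=lambda l: l.enrichment)
li, lj, gamma = spec.loops[0]
print(f"{len(loops)} loop call(s); top: bins ({top.bin_i}, {top.bin_j}) "
      f"span {top.span/1000:.0f} kb, enrichment {top.enrichment:.1f} "
      f"(planted ({li}, {lj}), gamma={gamma})")
print("note: weaker calls near the enrichment threshold are expected "
      "shot-noise at this depth; the planted loop dominates by rank")
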