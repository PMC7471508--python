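#!/usr/bin/env python
"""Call enhancer candidates in the distal loop anchor and scan their motifs.

Peaks overlapping the distal anchor of the strongest loop are merged
(gap <= 2 kb), scored by mean conservation, named Enh1..n, and their
sequences scanned against the toy TF profiles at relative score >= 0.90.
Every planted enhancer and its planted consensus must be recovered.
"""

import argparse
import json
from pathlib import Path

from t2c.domains import call_loops
from t2c.contacts import read_matrix
from t2c.motifs import annotate_enhancers, write_hits_tsv
from t2c.regulatory import (
    ConservationTrack,
    call_enhancer_candidates,
    read_peaks_bed,
    write_candidates,
)
from t2c.synthetic import toy_pwms

parser = argparse.ArgumentParser()
parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
parser.add_argument("--resolution", type=int, default=20_000)
args = parser.parse_args()

bm = read_matrix(args.out_dir / f"matrix_bin{args.resolution}")
loops = call_loops(bm)
anchor = max(loops, key=lambda l: l.enrichment).anchor_j
print(f"distal anchor of the top loop: {anchor}")

peaks = read_peaks_bed(args.sim_dir / "peaks.bed")
cons = ConservationTrack.from_bedgraph(args.sim_dir / "conservation.bedgraph")
candidates = call_enhancer_candidates(anchor, peaks, cons, merge_gap=2000)
write_candidates(candidates, args.out_dir / "enhancers.bed",
                 args.out_dir / "enhancers.json")
for c in candidates:
    print(f"  {c.name}: {c.interval} ({c.n_peaks} peak(s), "
          f"mean conservation {c.mean_conservation:.2f})")

hits = annotate_enhancers(candidates, args.sim_dir / "genome.fa", toy_pwms(),
                          threshold=0.90)
write_hits_tsv(hits, args.out_dir / "motif_hits.tsv")
print(f"{len(hits)} motif hit(s) at relative score >= 0.90")

truth = json.load(open(args.sim_dir / "truth.json"))
for enh in truth["enhancers"]:
    found = any(h.sequence_name == enh["name"] and h.motif_name == enh["motif"]
                and h.offset == enh["motif_offset"] for h in hits)
    print(f"  planted {enh['motif']} in {enh['name']} at offset "
          f"{enh['motif_offset']}: {'recovered' if found else 'MISSED'}")
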