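import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from t2c.contacts import assign_pairs, bin_matrix, load_pairs
from t2c.digest import APOI, FragmentMap, digest_region
from t2c.intervals import GenomicInterval
from t2c.motifs import annotate_enhancers
from t2c.regulatory import call_enhancer_candidates
from t2c.synthetic import (
    SimulationSpec,
    contact_probabilities,
    distal_anchors,
    make_genome,
    plant_tracks,
    simulate,
    simulate_pairs,
    toy_pwm_path,
    toy_pwms,
    truth_matrix,
)


class TestSimulationSpec:
    def test_yaml_round_trip(self, tmp_path):
        spec = SimulationSpec(seed=42, n_pairs=1234)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert SimulationSpec.from_yaml(path) == spec

    def test_unknown_keys_rejected(self, tmp_path):
        spec = SimulationSpec()
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        text = path.read_text() + "\nbogus_knob: 3\n"
        path.write_text(text)
        with pytest.raises(ValueError, match="bogus_knob"):
            SimulationSpec.from_yaml(path)

    def test_validation(self):
        with pytest.raises(ValueError, match="fragment"):
            SimulationSpec(target_fragment_size=10)
        with pytest.raises(ValueError, match="sorted"):
            SimulationSpec(tad_boundaries=[66, 33])
        with pytest.raises(ValueError, match="loop"):
            SimulationSpec(loops=[(40, 40, 8.0)], enhancers=[])
        with pytest.raises(ValueError, match="enhancer"):
            SimulationSpec(enhancers=[(1_990_000, 2_100_000, "SOX10")])


class TestMakeGenome:
    def test_target_fragment_size_hit(self):
        spec = SimulationSpec(
            region_length=1_000_000, target_fragment_size=500, seed=7,
            tad_boundaries=[], loops=[], enhancers=[],
        )
        _, fm = make_genome(spec)
        mean = len(fm.region) / len(fm)
        assert abs(mean - 500) / 500 < 0.15

    def test_deterministic_under_seed(self):
        spec = SimulationSpec(seed=9, region_length=200_000, tad_boundaries=[], loops=[], enhancers=[])
        seq1, _ = make_genome(spec)
        seq2, _ = make_genome(spec)
        assert seq1 == seq2
        other = SimulationSpec(seed=10, region_length=200_000, tad_boundaries=[], loops=[], enhancers=[])
        assert make_genome(other)[0] != seq1

    def test_truth_map_is_digest_of_emitted_sequence(self):
        spec = SimulationSpec(region_length=300_000, seed=3, tad_boundaries=[], loops=[], enhancers=[])
        seq, fm = make_genome(spec)
        redigested = digest_region(seq, APOI, spec.region)
        assert fm.fragments == redigested.fragments


class TestContactProbabilities:
    def test_pure_decay_ratio_closed_form(self):
        """With alpha=1 and no TAD/loop structure, w ~ 1/(d+1)."""
        spec = SimulationSpec(tad_boundaries=[], tau=0.0, loops=[], enhancers=[])
        probs = contact_probabilities(spec)
        assert probs[0, 2] / probs[0, 9] == pytest.approx(10 / 3)

    def test_toeplitz_without_structure(self):
        spec = SimulationSpec(tad_boundaries=[], tau=0.0, loops=[], enhancers=[])
        probs = contact_probabilities(spec)
        n = spec.n_bins
        for d in (2, 5, 40):
            vals = probs[np.arange(n - d), np.arange(d, n)]
            assert np.allclose(vals, vals[0])

    def test_planted_loop_multiplies_pixel(self):
        base = SimulationSpec(tad_boundaries=[], tau=0.0, loops=[], enhancers=[])
        looped = SimulationSpec(
            tad_boundaries=[], tau=0.0, loops=[(10, 40, 10.0)], enhancers=[]
        )
        p0 = contact_probabilities(base)
        p1 = contact_probabilities(looped)
        # compare unnormalised ratios via a reference pixel
        ratio = (p1[10, 40] / p1[0, 30]) / (p0[10, 40] / p0[0, 30])
        assert ratio == pytest.approx(10.0)

    def test_short_range_zero_and_normalised(self):
        spec = SimulationSpec()
        probs = contact_probabilities(spec)
        assert probs.sum() == pytest.approx(1.0)
        n = spec.n_bins
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        assert (probs[d <= 1] == 0).all()


class TestSimulatePairs:
    def test_pair_count_conserved(self, sim_manifest, default_spec):
        n_lines = sum(
            1 for line in open(sim_manifest["pairs"]) if not line.startswith("#")
        )
        assert n_lines == default_spec.n_pairs

    def test_pipeline_reproduces_truth_exactly(self, tmp_path):
        spec = SimulationSpec(seed=1, n_pairs=50_000)
        man = simulate(spec, tmp_path / "sim")
        fm = FragmentMap.from_bed(man["fragments"])
        recomputed = bin_matrix(
            assign_pairs(load_pairs(man["pairs"]), fm), spec.resolution
        )
        from t2c.contacts import read_matrix

        truth = read_matrix(man["truth_matrix"])
        assert (recomputed.counts != truth.counts).nnz == 0

    def test_truth_matrix_shortcut_agrees_with_full_draw(self):
        spec = SimulationSpec(region_length=400_000, tad_boundaries=[9],
                              loops=[(5, 15, 8.0)], enhancers=[],
                              n_pairs=5000, seed=31)
        seq, fm = make_genome(spec)
        _, full = simulate_pairs(spec, seq, fm)
        quick = truth_matrix(spec)
        assert (full.counts != quick.counts).nnz == 0

    def test_distance_decay_monotone(self):
        spec = SimulationSpec(
            tad_boundaries=[], tau=0.0, loops=[], enhancers=[],
            n_pairs=100_000, seed=13,
        )
        seq, fm = make_genome(spec)
        _, truth = simulate_pairs(spec, seq, fm)
        from t2c.domains import expected_by_distance

        exp = expected_by_distance(truth)
        d = np.arange(2, spec.n_bins - 1)
        rho = spearmanr(d, exp[2 : spec.n_bins - 1]).statistic
        assert rho < -0.9


class TestPlantTracks:
    def test_planted_enhancers_recovered(self, sim_manifest, default_spec):
        from t2c.regulatory import ConservationTrack, read_peaks_bed

        anchor = distal_anchors(default_spec)[0]
        peaks = read_peaks_bed(sim_manifest["peaks"])
        cons = ConservationTrack.from_bedgraph(sim_manifest["conservation"])
        candidates = call_enhancer_candidates(anchor, peaks, cons, merge_gap=2000)
        planted = sorted((s, e) for s, e, _ in default_spec.enhancers)
        assert [(c.interval.start, c.interval.end) for c in candidates] == planted
        assert all(c.mean_conservation == pytest.approx(1.0) for c in candidates)

    def test_planted_motifs_found_at_recorded_offsets(self, sim_manifest, default_spec):
        from t2c.regulatory import ConservationTrack, read_peaks_bed

        anchor = distal_anchors(default_spec)[0]
        peaks = read_peaks_bed(sim_manifest["peaks"])
        candidates = call_enhancer_candidates(anchor, peaks, merge_gap=2000)
        truth = json.load(open(sim_manifest["truth"]))
        hits = annotate_enhancers(
            candidates, sim_manifest["fasta"], toy_pwms(), threshold=0.90
        )
        for enh in truth["enhancers"]:
            matching = [
                h
                for h in hits
                if h.sequence_name == enh["name"]
                and h.motif_name == enh["motif"]
                and h.offset == enh["motif_offset"]
            ]
            assert matching, f"planted {enh['motif']} not found in {enh['name']}"
            assert max(h.relative for h in matching) == pytest.approx(1.0)

    def test_zero_enhancers_empty_outputs(self, tmp_path):
        spec = SimulationSpec(enhancers=[], n_pairs=1000, region_length=400_000,
                              tad_boundaries=[9], loops=[(5, 15, 8.0)], seed=2)
        man = simulate(spec, tmp_path / "sim")
        from t2c.regulatory import read_peaks_bed

        assert read_peaks_bed(man["peaks"]) == []
        anchor = distal_anchors(spec)[0]
        assert call_enhancer_candidates(anchor, []) == []

    def test_enhancer_outside_anchor_rejected(self):
        spec = SimulationSpec(enhancers=[], loops=[(40, 65, 8.0)])
        seq, _ = make_genome(spec)
        spec.enhancers = [(10_000, 11_000, "SOX10")]
        with pytest.raises(ValueError, match="anchor"):
            plant_tracks(spec, seq)

    def test_unknown_motif_rejected(self):
        spec = SimulationSpec(enhancers=[], loops=[(40, 65, 8.0)])
        seq, _ = make_genome(spec)
        spec.enhancers = [(1_304_000, 1_305_000, "NOSUCH")]
        with pytest.raises(KeyError, match="NOSUCH"):
            plant_tracks(spec, seq)


class TestFullDeterminism:
    def test_simulate_twice_byte_identical(self, tmp_path):
        spec = SimulationSpec(seed=21, region_length=400_000, n_pairs=5000,
                              tad_boundaries=[9], loops=[(5, 15, 8.0)],
                              enhancers=[(300_000, 301_000, "YY1")])
        man1 = simulate(spec, tmp_path / "a")
        man2 = simulate(spec, tmp_path / "b")
        for key in ("fasta", "pairs", "peaks", "conservation", "truth"):
            assert open(man1[key], "rb").read() == open(man2[key], "rb").read()
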