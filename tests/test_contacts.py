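import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from t2c.contacts import (
    BinAxis,
    ContactMatrix,
    ContactPair,
    FilterConfig,
    assign_pairs,
    bin_matrix,
    load_pairs,
    read_matrix,
    write_matrix,
    write_pairs,
)
from t2c.digest import FragmentMap
from t2c.intervals import GenomicInterval


def make_fm(n_fragments=10, frag_len=100, chrom="chr1"):
    region = GenomicInterval(chrom, 0, n_fragments * frag_len)
    cuts = [k * frag_len for k in range(1, n_fragments)]
    return FragmentMap(region, cuts)


def pair(pos1, pos2, chrom="chr1", mapq=60, rid="r"):
    return ContactPair(rid, chrom, pos1, "+", chrom, pos2, "-", mapq, mapq)


class TestLoadPairs:
    def test_header_only_file(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("#readID\tchrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tmapq1\tmapq2\n")
        assert list(load_pairs(p)) == []

    def test_single_line(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\tchr1\t5\t+\tchr1\t500\t-\t60\t60\n")
        (cp,) = load_pairs(p)
        assert cp.read_id == "r1" and cp.pos1 == 5 and cp.pos2 == 500

    def test_bad_position_names_line(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\tchr1\tabc\t+\tchr1\t500\t-\t60\t60\n")
        with pytest.raises(ValueError, match="line 1"):
            list(load_pairs(p))

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\tchr1\t5\t+\tchr1\t500\t-\t60\t60\nr2\tchr1\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            list(load_pairs(p))

    def test_round_trip(self, tmp_path):
        pairs = [pair(5, 500, rid="a"), pair(7, 900, rid="b")]
        p = tmp_path / "pairs.tsv"
        write_pairs(p, pairs)
        assert list(load_pairs(p)) == pairs


class TestAssignPairs:
    def test_same_fragment_dropped_and_tallied(self):
        fm = make_fm()
        cm = assign_pairs([pair(701, 750)], fm, FilterConfig())
        assert cm.counts.nnz == 0
        assert cm.metadata["dropped"]["same_fragment"] == 1

    def test_same_fragment_kept_on_diagonal_when_allowed(self):
        fm = make_fm()
        cm = assign_pairs([pair(701, 750)], fm, FilterConfig(drop_same_fragment=False))
        assert cm.counts[7, 7] == 1 and cm.total == 1

    def test_symmetric_increment(self):
        fm = make_fm()
        cm = assign_pairs([pair(201, 701)], fm)
        assert cm.counts[2, 7] == 1 and cm.counts[7, 2] == 1
        assert cm.total == 1

    def test_adjacent_filter_both_settings(self):
        fm = make_fm()
        kept = assign_pairs([pair(301, 401)], fm, FilterConfig())
        assert kept.counts[3, 4] == 1
        dropped = assign_pairs(
            [pair(301, 401)], fm, FilterConfig(drop_adjacent_fragments=True)
        )
        assert dropped.counts.nnz == 0
        assert dropped.metadata["dropped"]["adjacent"] == 1

    def test_low_mapq_and_trans_and_off_region_tallied(self):
        fm = make_fm()
        pairs = [
            pair(201, 701, mapq=5),
            ContactPair("t", "chr1", 201, "+", "chr9", 701, "-", 60, 60),
            pair(201, 5000),
        ]
        cm = assign_pairs(pairs, fm)
        d = cm.metadata["dropped"]
        assert (d["low_mapq"], d["trans"], d["off_region"]) == (1, 1, 1)
        assert cm.metadata["n_kept"] == 0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 200))
    @settings(max_examples=20, deadline=None)
    def test_tally_completeness_and_symmetry(self, seed, n_pairs):
        """input count == kept + sum(drop reasons); matrix always symmetric."""
        rng = np.random.default_rng(seed)
        fm = make_fm(20, 50)
        pairs = [
            ContactPair(
                f"r{k}",
                rng.choice(["chr1", "chr2"], p=[0.9, 0.1]),
                int(rng.integers(1, 1500)),
                "+",
                "chr1",
                int(rng.integers(1, 1500)),
                "-",
                int(rng.integers(0, 61)),
                int(rng.integers(0, 61)),
            )
            for k in range(n_pairs)
        ]
        cm = assign_pairs(pairs, fm)
        assert cm.metadata["n_input"] == n_pairs
        assert cm.metadata["n_kept"] + sum(cm.metadata["dropped"].values()) == n_pairs
        assert (cm.counts != cm.counts.T).nnz == 0
        assert cm.total == cm.metadata["n_kept"]


class TestBinMatrix:
    def test_midpoint_binning_example(self):
        # fragments [0,10000) and [20000,30000): midpoints 5000 and 25000
        region = GenomicInterval("chr1", 0, 30000)
        fm = FragmentMap(region, [10000, 20000])
        cm = assign_pairs([pair(5, 25000)], fm)
        bm = bin_matrix(cm, 20000)
        assert bm.counts[0, 1] == 1 and bm.counts[1, 0] == 1

    def test_total_conserved(self):
        rng = np.random.default_rng(3)
        fm = make_fm(30, 73)
        pairs = [
            pair(int(rng.integers(1, 2190)), int(rng.integers(1, 2190)), rid=f"r{k}")
            for k in range(500)
        ]
        cm = assign_pairs(pairs, fm)
        for res in (1, 100, 500, 1000):
            assert bin_matrix(cm, res).total == cm.total

    def test_resolution_at_least_region_gives_1x1(self):
        fm = make_fm(10, 100)
        cm = assign_pairs([pair(5, 701), pair(105, 901)], fm)
        bm = bin_matrix(cm, 10_000_000)
        assert bm.n == 1 and bm.counts[0, 0] == cm.total

    def test_identity_limit_unit_fragments(self):
        """1-bp binning of a matrix over 1-bp fragments is the identity."""
        region = GenomicInterval("chr1", 0, 6)
        fm = FragmentMap(region, [1, 2, 3, 4, 5])
        cm = assign_pairs([pair(1, 4), pair(2, 6)], fm)
        bm = bin_matrix(cm, 1)
        assert (bm.counts != cm.counts).nnz == 0


class TestMatrixIO:
    def _random_matrix(self, seed=5):
        rng = np.random.default_rng(seed)
        axis = BinAxis(GenomicInterval("chr1", 0, 100_000), 10_000)
        n = axis.n_bins
        upper = sp.random(n, n, density=0.3, random_state=42, data_rvs=lambda k: rng.integers(1, 50, k))
        upper = sp.triu(upper.astype(np.int64))
        full = (upper + sp.triu(upper, k=1).T).tocsr()
        return ContactMatrix(axis, full, {"level": "binned", "resolution": 10_000})

    def test_round_trip_identity(self, tmp_path):
        cm = self._random_matrix()
        write_matrix(cm, tmp_path / "m")
        back = read_matrix(tmp_path / "m")
        assert (back.counts != cm.counts).nnz == 0
        assert back.metadata == cm.metadata
        assert back.axis.resolution == cm.axis.resolution

    def test_out_of_axis_triplet_rejected(self, tmp_path):
        cm = self._random_matrix()
        write_matrix(cm, tmp_path / "m")
        with open(tmp_path / "m.triplets.tsv", "a") as fh:
            fh.write("99\t99\t1\n")
        with pytest.raises(ValueError, match="outside axis"):
            read_matrix(tmp_path / "m")

    def test_empty_matrix_round_trip(self, tmp_path):
        axis = BinAxis(GenomicInterval("chr1", 0, 1000), 100)
        cm = ContactMatrix(
            axis, sp.csr_matrix((10, 10), dtype=np.int64), {"note": "empty"}
        )
        write_matrix(cm, tmp_path / "e")
        back = read_matrix(tmp_path / "e")
        assert back.counts.nnz == 0 and back.metadata == {"note": "empty"}
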