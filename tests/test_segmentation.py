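import numpy as np
import pytest

from smallder import (
    GlobalParams,
    HmmParams,
    IrParams,
    NaiveParams,
    annotation_candidates,
    hmm_segment,
    ir_segment,
    naive_segment,
    viterbi_two_state,
)
from smallder.rle import RunLengthTrack

from oracles import brute_force_ir, brute_force_viterbi, dense_viterbi, expand_path

WIDE = GlobalParams(min_size=1, max_size=10**9)


def track(values, lengths=None, chrom="chr1"):
    return RunLengthTrack(chrom, values, lengths or [1] * len(values))


def full_mask(n):
    return RunLengthTrack("chr1", [1.0], [n])


class TestNaive:
    def test_same_sign_runs_within_distance_merge(self):
        v = np.zeros(300)
        v[99:120] = 1.0
        v[169:190] = 1.2
        lfc = RunLengthTrack.from_array("chr1", v)
        out = naive_segment(lfc, full_mask(300), NaiveParams(), WIDE)
        assert [(r.start, r.end, r.sign) for r in out] == [(100, 190, "+")]

    def test_opposite_sign_runs_never_merge(self):
        v = np.zeros(300)
        v[99:120] = 1.0
        v[169:190] = -1.0
        lfc = RunLengthTrack.from_array("chr1", v)
        out = naive_segment(lfc, full_mask(300), NaiveParams(), WIDE)
        assert [(r.start, r.end, r.sign) for r in out] == [
            (100, 120, "+"),
            (170, 190, "-"),
        ]

    def test_short_region_dropped_after_merging(self):
        v = np.zeros(100)
        v[10:20] = 2.0  # 10 nt < min_size 18
        lfc = RunLengthTrack.from_array("chr1", v)
        out = naive_segment(lfc, full_mask(100), NaiveParams(), GlobalParams())
        assert out == []

    def test_zero_distance_returns_exact_runs(self, rng):
        v = rng.choice([0.0, 0.0, 0.7, -0.7], size=200)
        lfc = RunLengthTrack.from_array("chr1", v)
        out = naive_segment(
            lfc, full_mask(200), NaiveParams(max_distance=0), WIDE
        )
        # reconstruct expected maximal same-sign runs densely
        expected = []
        i = 0
        while i < 200:
            if abs(v[i]) >= 0.5:
                s = np.sign(v[i])
                j = i
                while j + 1 < 200 and abs(v[j + 1]) >= 0.5 and np.sign(v[j + 1]) == s:
                    j += 1
                expected.append((i + 1, j + 1, "+" if s > 0 else "-"))
                i = j + 1
            else:
                i += 1
        assert [(r.start, r.end, r.sign) for r in out] == expected

    def test_masked_positions_cannot_seed_regions(self):
        v = np.full(100, 2.0)
        lfc = RunLengthTrack.from_array("chr1", v)
        mask = RunLengthTrack("chr1", [0.0, 1.0], [50, 50])
        out = naive_segment(lfc, mask, NaiveParams(max_distance=0), WIDE)
        assert [(r.start, r.end) for r in out] == [(51, 100)]


class TestViterbi:
    def test_all_significant_path_is_all_diff(self):
        got = expand_path(viterbi_two_state([(0.01, 8)], HmmParams()))
        assert got == brute_force_viterbi([0.01] * 8, HmmParams()) == [1] * 8

    def test_all_ones_path_is_all_null(self):
        assert viterbi_two_state([(1.0, 25)], HmmParams()) == [(0, 25)]

    def test_transition_point_matches_brute_force(self):
        obs = [1.0, 1.0, 1.0] + [0.01] * 5
        got = expand_path(viterbi_two_state([(1.0, 3), (0.01, 5)], HmmParams()))
        assert got == brute_force_viterbi(obs, HmmParams()) == [0] * 3 + [1] * 5

    def test_sparse_equals_dense_on_random_tracks(self, rng):
        p = HmmParams()
        for _ in range(100):
            obs = []
            total = 0
            while total < 200:
                length = int(rng.integers(1, 40))
                v = 1.0 if rng.random() < 0.5 else float(rng.random())
                obs.append((v, length))
                total += length
            dense = [v for v, n in obs for _ in range(n)]
            assert expand_path(viterbi_two_state(obs, p)) == dense_viterbi(dense, p)

    def test_sparse_equals_dense_for_random_parameters(self, rng):
        for _ in range(50):
            p = HmmParams(
                tp1=float(rng.uniform(1e-4, 0.4)),
                tp2=float(rng.uniform(1e-6, 0.4)),
                pt=float(rng.uniform(0.05, 0.5)),
                ep=float(rng.uniform(0.55, 0.99)),
                start_prob_diff=float(rng.uniform(1e-4, 0.5)),
            )
            obs = [
                (1.0 if rng.random() < 0.5 else float(rng.random()),
                 int(rng.integers(1, 30)))
                for _ in range(int(rng.integers(1, 10)))
            ]
            dense = [v for v, n in obs for _ in range(n)]
            assert expand_path(viterbi_two_state(obs, p)) == dense_viterbi(dense, p)

    def test_rejects_out_of_range_observations(self):
        with pytest.raises(ValueError):
            viterbi_two_state([(1.5, 3)], HmmParams())


class TestHmmSegment:
    def test_constant_one_track_yields_nothing(self):
        assert hmm_segment(track([1.0], [500]), HmmParams(), GlobalParams()) == []

    def test_single_island_recovered_exactly(self):
        pv = RunLengthTrack("chr1", [1.0, 1e-6, 1.0], [200, 50, 200])
        out = hmm_segment(pv, HmmParams(), GlobalParams())
        assert [(r.start, r.end, r.method) for r in out] == [(201, 250, "hmm")]
        # agreement with the dense oracle
        dense = dense_viterbi([1.0] * 200 + [1e-6] * 50 + [1.0] * 200, HmmParams())
        assert dense == [0] * 200 + [1] * 50 + [0] * 200

    def test_short_island_dropped_by_size_filter(self):
        pv = RunLengthTrack("chr1", [1.0, 1e-6, 1.0], [200, 10, 200])
        assert hmm_segment(pv, HmmParams(), GlobalParams()) == []


class TestIr:
    def test_shallow_dip_is_bridged(self):
        lfc = track([2, 2, 0.4, 2, 2])
        out = ir_segment(lfc, full_mask(5), IrParams(), WIDE)
        assert [(r.start, r.end) for r in out] == [(1, 5)]

    def test_long_gap_splits(self):
        lfc = track([2.0] * 2 + [0.0] * 10 + [2.0] * 2)
        out = ir_segment(lfc, full_mask(14), IrParams(), WIDE)
        assert [(r.start, r.end) for r in out] == [(1, 2), (13, 14)]

    def test_flat_zero_track_yields_nothing(self):
        assert ir_segment(track([0.0], [50]), full_mask(50), IrParams(), WIDE) == []

    def test_opposite_signs_processed_separately(self):
        v = [2.0] * 5 + [-2.0] * 5
        out = ir_segment(track(v), full_mask(10), IrParams(), WIDE)
        assert [(r.start, r.end, r.sign) for r in out] == [
            (1, 5, "+"),
            (6, 10, "-"),
        ]

    @pytest.mark.parametrize("signed_area", [False, True])
    def test_matches_bruteforce_on_random_step_tracks(self, rng, signed_area):
        # dyadic values keep the threshold comparisons exact in binary
        # floating point, so implementation and oracle agree bit-for-bit
        choices = [0.0, 0.25, 0.75, 1.0, 1.5, 2.5, 3.0]
        for _ in range(100):
            nruns = int(rng.integers(1, 50))
            vals = rng.choice(choices, nruns)
            lens = rng.integers(1, 12, nruns)
            t = RunLengthTrack("chr1", vals, lens)
            got = sorted(
                (r.start, r.end)
                for r in ir_segment(
                    t, full_mask(t.total_length), IrParams(), WIDE,
                    signed_area=signed_area,
                )
            )
            want = brute_force_ir(t.to_array(), 0.5, signed_area=signed_area)
            assert got == want


class TestAnnotation:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tmiRNA\t101\t122\t.\t+\t.\tID=mir1\n"
        "chr1\tsrc\tmiRNA\t201\t228\t.\t-\t.\tID=mir2\n"
        "chr1\tsrc\tmiRNA\t301\t322\t.\t+\t.\tID=mir3\n"
    )

    def test_three_records_three_candidates(self, tmp_path):
        f = tmp_path / "ann.gff3"
        f.write_text(self.GFF)
        out = annotation_candidates(f, GlobalParams())
        assert [(r.start, r.end, r.method) for r in out] == [
            (101, 122, "annotation"),
            (201, 228, "annotation"),
            (301, 322, "annotation"),
        ]

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "ann.gff3"
        f.write_text("##gff-version 3\n")
        assert annotation_candidates(f, GlobalParams()) == []

    def test_duplicate_coordinates_deduplicated(self, tmp_path):
        f = tmp_path / "ann.gff3"
        f.write_text(
            "chr1\tsrc\tmiRNA\t101\t122\t.\t+\t.\tID=a\n"
            "chr1\tsrc\tmiRNA\t101\t122\t.\t-\t.\tID=b\n"
        )
        assert len(annotation_candidates(f, GlobalParams())) == 1

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            annotation_candidates(tmp_path / "none.gff3", GlobalParams())


def test_candidates_respect_size_bounds_and_mask(rng):
    """Every emitted candidate obeys the size filter and the depth mask."""
    g = GlobalParams(min_size=5, max_size=40)
    v = rng.choice([0.0, 0.0, 0.8, 2.0, -1.0], size=500)
    lfc = RunLengthTrack.from_array("chr1", v)
    mask_arr = (rng.random(500) < 0.8).astype(float)
    mask = RunLengthTrack.from_array("chr1", mask_arr)
    for segs in (
        naive_segment(lfc, mask, NaiveParams(max_distance=0), g),
        ir_segment(lfc, mask, IrParams(), g),
    ):
        for r in segs:
            assert g.min_size <= r.length <= g.max_size
            # no region may *start or end* outside the mask support
            assert mask_arr[r.start - 1] == 1.0 and mask_arr[r.end - 1] == 1.0
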