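"""DMR caller: pileups, smoothing, peaks, permutation thresholds, classification."""

from itertools import combinations

import numpy as np
import pytest

from xtalk import dmr as dm
from xtalk import simulate as sim


def brute_force_pileup(reads, seq_len, extend=0, library_size=None):
    """Per-position membership count, the slow way."""
    lib = library_size or len(reads)
    track = np.zeros(seq_len)
    for s, e in reads:
        track[s : min(e + extend, seq_len)] += 1
    return track * 1e6 / lib


def brute_force_windowed_mean(values, window):
    n = len(values)
    left, right = (window - 1) // 2, window // 2
    return np.array(
        [np.mean(values[max(0, i - left) : min(n, i + right + 1)]) for i in range(n)]
    )


class TestCoverageTrack:
    def test_single_read(self):
        track = dm.coverage_track(np.array([[100, 150]]), 1000, library_size=10**6)
        assert (track[100:150] == 1.0).all()
        assert track[:100].sum() == 0 and track[150:].sum() == 0

    def test_empty_reads(self):
        assert dm.coverage_track(np.empty((0, 2)), 500, library_size=1).sum() == 0

    def test_matches_brute_force(self, rng):
        starts = rng.integers(0, 1900, size=500)
        reads = np.column_stack([starts, starts + rng.integers(1, 100, size=500)])
        reads[:, 1] = np.minimum(reads[:, 1], 2000)
        np.testing.assert_allclose(
            dm.coverage_track(reads, 2000), brute_force_pileup(reads, 2000)
        )

    def test_extension_matches_brute_force(self, rng):
        starts = rng.integers(0, 1950, size=200)
        reads = np.column_stack([starts, starts + 20])
        np.testing.assert_allclose(
            dm.coverage_track(reads, 2000, extend=30),
            brute_force_pileup(reads, 2000, extend=30),
        )

    def test_out_of_bounds_read_rejected(self):
        with pytest.raises(ValueError, match=r"\[990, 1010\)"):
            dm.coverage_track(np.array([[990, 1010]]), 1000)


class TestSmoothedDifferential:
    def test_identical_tracks_are_zero(self, rng):
        t = rng.random(500)
        assert np.abs(dm.smoothed_differential(t, t)).max() == 0

    def test_rectangle_interior_and_edge_taper(self):
        treat = np.zeros(400)
        treat[150:250] = 2.0
        ctrl = np.zeros(400)
        out = dm.smoothed_differential(treat, ctrl, window=10)
        assert (out[160:240] == 2.0).all()  # interior of the 100 bp rectangle
        np.testing.assert_allclose(out, brute_force_windowed_mean(treat, 10))

    def test_uniform_offset_sign_convention(self):
        treat, ctrl = np.zeros(100), np.ones(100)
        out = dm.smoothed_differential(treat, ctrl)
        assert np.allclose(out, -1.0)

    def test_random_profile_matches_oracle(self, rng):
        diff = rng.normal(size=3000)
        np.testing.assert_allclose(
            dm.sliding_mean(diff, 10), brute_force_windowed_mean(diff, 10), atol=1e-9
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dm.smoothed_differential(np.zeros(10), np.zeros(11))


class TestCandidatePeaks:
    def test_flat_profile_yields_nothing(self):
        assert dm.find_candidate_peaks(np.zeros(100)) == []

    def test_single_plateau(self):
        prof = np.zeros(300)
        prof[100:150] = 2.0
        (peak,) = dm.find_candidate_peaks(prof)
        assert (peak.start, peak.end, peak.width, peak.height, peak.sign) == (
            100, 150, 50, 2.0, 1,
        )

    def test_opposite_sign_runs_not_merged(self):
        prof = np.concatenate([np.full(50, 1.0), np.full(50, -1.0)])
        peaks = dm.find_candidate_peaks(prof)
        assert [p.sign for p in peaks] == [1, -1]
        assert peaks[0].end == peaks[1].start == 50

    def test_runs_match_brute_force(self, rng):
        prof = np.round(rng.normal(size=5000), 1)
        peaks = dm.find_candidate_peaks(prof, epsilon=0.5)
        # brute force: scan positions, accumulate runs
        expected = []
        cur = None
        for i, v in enumerate(prof):
            s = 1 if v > 0.5 else (-1 if v < -0.5 else 0)
            if cur is not None and (s != cur[2]):
                expected.append(cur)
                cur = None
            if s != 0 and cur is None:
                cur = [i, i + 1, s]
            elif s != 0:
                cur[1] = i + 1
        if cur is not None:
            expected.append(cur)
        assert [(p.start, p.end, p.sign) for p in peaks] == [tuple(e) for e in expected]
        for p in peaks:
            assert p.height == np.abs(prof[p.start : p.end]).max()


class TestPermutationThresholds:
    def test_seeded_determinism(self, rng):
        starts = rng.integers(0, 900, size=400)
        pool = np.column_stack([starts, starts + 50])
        a = dm.permutation_thresholds(pool, 100, 100, 1000, iterations=20, seed=5)
        b = dm.permutation_thresholds(pool, 100, 100, 1000, iterations=20, seed=5)
        assert (a.w_max, a.h_max) == (b.w_max, b.h_max)

    def test_running_maximum_monotone_in_iterations(self, rng):
        starts = rng.integers(0, 900, size=400)
        pool = np.column_stack([starts, starts + 50])
        results = [
            dm.permutation_thresholds(pool, 100, 100, 1000, iterations=k, seed=7)
            for k in (5, 20, 60)
        ]
        for a, b in zip(results, results[1:]):
            assert b.w_max >= a.w_max and b.h_max >= a.h_max

    def test_never_exceeds_exhaustive_split_maxima(self):
        """With 6 pooled reads, all C(6,3) splits bound the permutation maxima."""
        pool = np.array([[0, 30], [20, 50], [40, 70], [10, 40], [60, 90], [35, 65]])
        w_best, h_best = 0, 0.0
        for idx in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in idx]
            t1 = dm.coverage_track(pool[list(idx)], 100)
            t2 = dm.coverage_track(pool[rest], 100)
            for p in dm.find_candidate_peaks(dm.smoothed_differential(t1, t2)):
                w_best = max(w_best, p.width)
                h_best = max(h_best, p.height)
        thr = dm.permutation_thresholds(pool, 3, 3, 100, iterations=100, seed=1)
        assert thr.w_max <= w_best and thr.h_max <= h_best + 1e-9

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            dm.permutation_thresholds(np.array([[0, 10]]), 1, 1, 100)


class TestCallDmrs:
    THR = dm.NullThresholds(w_max=50, h_max=2.0, iterations=100, seed=0)

    @pytest.mark.parametrize(
        "width,height,kept",
        [(60, 3.0, True), (40, 3.0, False), (60, 1.5, False), (50, 2.5, False)],
    )
    def test_and_rule_is_strict_on_both(self, width, height, kept):
        peak = dm.Peak(0, width, height, -1)
        assert (dm.call_dmrs([peak], self.THR) == [peak]) is kept

    def test_or_rule(self):
        peak = dm.Peak(0, 40, 3.0, 1)
        assert dm.call_dmrs([peak], self.THR, rule="or") == [peak]


class TestClassifyDmrs:
    def _profiles(self, deltas_by_dmr, length=300):
        """Constant differential profiles realizing given per-DMR deltas."""
        profiles = {t: np.zeros(length) for t in ("T3", "CORT", "T3CORT")}
        dmrs = []
        for i, deltas in enumerate(deltas_by_dmr):
            s, e = 50 + i * 100, 100 + i * 100
            for t, v in zip(("T3", "CORT", "T3CORT"), deltas):
                profiles[t][s:e] = v
            dmrs.append(dm.DMR(start=s, end=e, height=3.0, sign=-1, treatments=("T3",)))
        return dmrs, profiles

    def test_symmetric_and_cotreatment_codes(self):
        dmrs, profiles = self._profiles([(-3, 0, -3), (0, 0, -3)])
        out = dm.classify_dmrs(dmrs, profiles)
        assert [d.code for d in out] == ["d_n_d", "n_n_d"]
        assert [d.category for d in out] == ["T3", "XTALK"]
        assert out[0].deltas == (-3.0, 0.0, -3.0)

    def test_empty_input(self):
        assert dm.classify_dmrs([], {}) == []


@pytest.fixture(scope="module")
def planted_run():
    codes = ("d_n_d", "d_d_d", "n_n_d", "d_n_n", "d_n_u", "n_d_d")
    sign = {"d": -0.8, "u": 0.8, "n": 0.0}
    truth = [
        sim.MethylationTruth(
            "chr1", 6000 + i * 12_000, 6800 + i * 12_000,
            tuple(sign[c] for c in codes[i % 6].split("_")),
        )
        for i in range(8)
    ]
    reads = sim.simulate_methylome(100_000, truth, 100_000, fragment_len=50, seed=21)
    result = dm.detect_dmrs(reads, 100_000, iterations=100, seed=31)
    return truth, result


class TestFullCaller:
    def test_every_dmr_was_a_candidate_peak(self, planted_run):
        truth, result = planted_run
        for t in ("T3", "CORT", "T3CORT"):
            peaks = dm.find_candidate_peaks(result.profiles[t])
            called = [d for d in result.dmrs if t in d.treatments]
            assert len(called) <= len(peaks)

    def test_planted_regions_recovered(self, planted_run):
        truth, result = planted_run
        recovered = 0
        for r in truth:
            best = max(
                (
                    (min(r.end, d.end) - max(r.start, d.start))
                    / (max(r.end, d.end) - min(r.start, d.start))
                    for d in result.dmrs
                ),
                default=0.0,
            )
            recovered += best >= 0.5
        assert recovered >= 7  # >= 90% of 8 planted regions

    def test_null_run_is_empty(self):
        reads = sim.simulate_methylome(50_000, [], 50_000, fragment_len=50, seed=3)
        result = dm.detect_dmrs(reads, 50_000, iterations=100, seed=13)
        assert result.dmrs == []

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            dm.detect_dmrs({"CTRL": np.zeros((0, 2))}, 1000)


class TestMergeIntervals:
    def test_union_of_overlapping(self):
        assert dm.merge_intervals([(0, 10), (5, 20), (30, 40)]) == [(0, 20), (30, 40)]

    def test_adjacent_not_merged(self):
        assert dm.merge_intervals([(0, 10), (10, 20)]) == [(0, 10), (10, 20)]
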