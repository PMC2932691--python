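"""Window scanning, PEP calibration, FDR thresholding and profile assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteocnv.profile import (build_profile, genome_profile, pep_transform,
                               profile_segments, profile_to_copy_number,
                               profiled_correlation, randomize_genome, scan_chromosome,
                               segment_recovery, significance_threshold, window_sizes)
from proteocnv.simulate import place_random_segments, simulate_planted_track


class TestWindowSizes:
    @pytest.mark.parametrize("length, expected", [
        (8, [3, 4, 6, 8]),
        (3, [3]),
        (12, [3, 4, 6, 8, 12]),
    ])
    def test_sqrt2_ladder(self, length, expected):
        assert window_sizes(length) == expected

    def test_always_capped_by_and_including_chromosome_length(self):
        sizes = window_sizes(100)
        assert sizes[-1] == 100 and max(sizes) == 100

    @given(st.integers(3, 2000))
    def test_sorted_unique_and_bounded(self, length):
        sizes = window_sizes(length)
        assert sizes == sorted(set(sizes))
        assert sizes[0] == 3 and sizes[-1] == length

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            window_sizes(2)


class TestScan:
    def test_zero_variance_zero_mean_window_has_p_one(self):
        w = scan_chromosome(np.zeros(3), [3])
        assert w.loc[0, "p_value"] == 1.0 and w.loc[0, "mean"] == 0.0

    def test_zero_variance_nonzero_mean_window_has_minimal_p(self):
        w = scan_chromosome(np.ones(3), [3])
        assert 0 < w.loc[0, "p_value"] <= np.finfo(float).tiny

    def test_t_statistic_matches_textbook_computation(self):
        # window {0.5, 1.0, 1.5}: t = 1.0 / (0.5/sqrt(3)) = 3.4641, df = 2,
        # two-sided p = 1 - t/sqrt(2 + t^2) = 0.074180
        w = scan_chromosome(np.array([0.5, 1.0, 1.5]), [3])
        assert w.loc[0, "p_value"] == pytest.approx(0.0741799, abs=1e-5)
        assert w.loc[0, "median"] == 1.0

    def test_window_counts_per_size(self):
        w = scan_chromosome(np.arange(10, dtype=float))
        for s in window_sizes(10):
            assert (w["size"] == s).sum() == 10 - s + 1


class TestRandomize:
    def test_preserves_multiset_and_moments(self, rng):
        values = rng.normal(0, 1, 500)
        perm = randomize_genome(values, np.random.default_rng(1))
        assert np.array_equal(np.sort(perm), np.sort(values))
        assert perm.mean() == pytest.approx(values.mean())
        assert perm.var() == pytest.approx(values.var())

    def test_seed_determinism(self, rng):
        values = rng.normal(0, 1, 100)
        a = randomize_genome(values, np.random.default_rng(7))
        b = randomize_genome(values, np.random.default_rng(7))
        assert np.array_equal(a, b)


def _windows_from_p(p, size=10):
    n = len(p)
    return pd.DataFrame({"chromosome": "1", "start": np.arange(n),
                         "end": np.arange(n) + size, "size": size,
                         "mean": 0.0, "median": 0.0, "p_value": p})


class TestPep:
    def test_equal_densities_give_pep_near_one(self):
        p = np.linspace(0.01, 1.0, 1000)
        obs = _windows_from_p(p)
        null = _windows_from_p(np.tile(p, 10))
        obs_pep, null_pep = pep_transform(obs, null, n_permutations=10)
        assert obs_pep.mean() > 0.9
        assert (obs_pep <= 1.0).all()

    def test_tenfold_observed_excess_gives_pep_near_tenth(self):
        p = np.linspace(0.01, 1.0, 1000)
        obs = _windows_from_p(p)
        null = _windows_from_p(np.tile(p[::10], 10))  # null density 10x lower
        obs_pep, _ = pep_transform(obs, null, n_permutations=10)
        assert obs_pep.mean() == pytest.approx(0.1, abs=0.02)

    def test_pure_null_scan_average_pep_near_one(self, rng):
        values = rng.normal(0, 0.3, 600)
        obs = scan_chromosome(values, [12])
        obs.insert(0, "chromosome", "1")
        prng = np.random.default_rng(5)
        null = pd.concat([scan_chromosome(prng.permutation(values), [12])
                          for _ in range(10)], ignore_index=True)
        null.insert(0, "chromosome", "1")
        obs_pep, _ = pep_transform(obs, null, n_permutations=10)
        assert obs_pep.mean() > 0.7  # 1 within binning error

    def test_pep_monotone_in_p_within_stratum(self, rng):
        values = rng.normal(0, 0.3, 400)
        obs = scan_chromosome(values, [8])
        obs.insert(0, "chromosome", "1")
        prng = np.random.default_rng(6)
        null = pd.concat([scan_chromosome(prng.permutation(values), [8])
                          for _ in range(10)], ignore_index=True)
        null.insert(0, "chromosome", "1")
        obs_pep, _ = pep_transform(obs, null, n_permutations=10)
        order = np.argsort(obs["p_value"].to_numpy())
        assert (np.diff(obs_pep[order]) >= -1e-12).all()


class TestThreshold:
    def test_fdr_zero_gives_empty_set(self):
        cutoff, sig = significance_threshold(np.array([0.001, 0.5]),
                                             np.array([0.9]), 10, fdr=0.0)
        assert not sig.any() and np.isnan(cutoff)

    def test_pure_noise_yields_empty_or_tiny_significant_set(self, rng):
        track = simulate_planted_track(2, 300, None, 0.3, seed=4)
        res = genome_profile(track, seed=40)
        assert res.windows["significant"].mean() <= 0.02

    def test_planted_segment_produces_overlapping_significant_window(self):
        segs = pd.DataFrame({"chromosome": ["1"], "start": [100], "end": [120],
                             "mean": [1.0]})
        track = simulate_planted_track(1, 300, segs, 0.3, seed=8)
        res = genome_profile(track, seed=80)
        sig = res.significant_windows
        overlapping = sig[(sig["chromosome"] == "1") & (sig["start"] < 120)
                          & (sig["end"] > 100)]
        assert len(overlapping) > 0
        assert (overlapping["median"] > 0).any()


def _sig(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "size", "median"])


class TestBuildProfile:
    def test_single_window_paints_its_span_only(self):
        prof = build_profile(_sig([("1", 10, 30, 20, 0.9)]), {"1": 50})
        values, win = prof["1"]
        assert (values[10:30] == 0.9).all()
        assert (values[:10] == 0).all() and (values[30:] == 0).all()
        assert (win[10:30] == 0).all() and (win[0] == -1)

    def test_max_deviation_wins_on_overlap(self):
        prof = build_profile(_sig([("1", 0, 20, 20, 0.5), ("1", 10, 30, 20, -0.2)]),
                             {"1": 40})
        values, _ = prof["1"]
        assert (values[10:20] == 0.5).all()   # |0.5| > |-0.2|
        assert (values[20:30] == -0.2).all()

    def test_tie_broken_by_smaller_window(self):
        prof = build_profile(_sig([("1", 0, 30, 30, 0.5), ("1", 10, 16, 6, 0.5)]),
                             {"1": 40})
        _, win = prof["1"]
        assert (win[10:16] == 1).all() and win[0] == 0

    def test_idempotent_and_monotone_under_window_addition(self):
        base = _sig([("1", 5, 15, 10, 0.8), ("1", 20, 26, 6, -0.4)])
        first = build_profile(base, {"1": 40})["1"][0]
        again = build_profile(base, {"1": 40})["1"][0]
        assert np.array_equal(first, again)
        more = build_profile(pd.concat([base, _sig([("1", 12, 22, 10, 0.3)])],
                                       ignore_index=True), {"1": 40})["1"][0]
        assert not ((first != 0) & (more == 0)).any()


class TestProfileOutputs:
    @pytest.mark.parametrize("log2, copies", [(-1.0, 1.0), (0.0, 2.0), (1.0, 4.0)])
    def test_copy_number_conversion(self, log2, copies):
        assert profile_to_copy_number(log2) == copies

    def test_profiled_correlation_of_identical_tracks_is_one(self, rng):
        x = rng.normal(0, 1, 100)
        assert profiled_correlation(x, x) == pytest.approx(1.0)

    def test_all_zero_profile_flagged(self, rng):
        with pytest.warns(UserWarning):
            assert np.isnan(profiled_correlation(np.zeros(50), rng.normal(0, 1, 50)))

    def test_profile_zero_exactly_where_no_window_contributes(self):
        segs = pd.DataFrame({"chromosome": ["1"], "start": [50], "end": [90],
                             "mean": [1.2]})
        track = simulate_planted_track(2, 200, segs, 0.3, seed=13)
        res = genome_profile(track, seed=130)
        prof = res.profile
        assert ((prof["profile_log2"] == 0) == (prof["window_id"] == -1)).all()

    def test_segments_are_maximal_same_sign_runs(self):
        profile = pd.DataFrame({
            "chromosome": "1", "position": (np.arange(10) + 1) * 10,
            "gene": [f"g{i}" for i in range(10)],
            "profile_log2": [0, 0.5, 0.5, 0, -0.3, -0.2, 0, 0.1, 0.1, 0.1]})
        segs = profile_segments(profile)
        assert list(segs["direction"]) == ["amp", "del", "amp"]
        assert list(segs["start_index"]) == [1, 4, 7]
        assert list(segs["end_index"]) == [3, 6, 10]


class TestPlantedRecovery:
    def test_strong_segments_detected_with_correct_sign(self):
        """Planted segments (|mean| >= 2x noise sd) are overlapped by
        same-sign profile calls in nearly all cases."""
        total = found = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            segs = place_random_segments(rng, 5, 300, 6)
            track = simulate_planted_track(5, 300, segs, 0.3, seed)
            res = genome_profile(track, seed=seed + 500)
            rec = segment_recovery(res.profile, segs)
            total += len(rec)
            found += int(rec["start_error"].notna().sum())
        assert found / total >= 0.9

    def test_correlation_amplification_on_regional_data(self):
        """In the noisy regime that motivates profiling (per-gene noise
        comparable to the regional shifts), averaging over significant
        regions raises the correlation with the underlying regional
        means (the raw vs profiled contrast)."""
        rng = np.random.default_rng(3)
        segs = place_random_segments(rng, 5, 300, 6)
        track = simulate_planted_track(5, 300, segs, 0.9, seed=3)
        truth = np.zeros(len(track))
        ordered = track.reset_index(drop=True)
        for seg in segs.itertuples():
            idx = ordered.index[ordered["chromosome"] == seg.chromosome][seg.start:seg.end]
            truth[idx] = seg.mean
        res = genome_profile(track, seed=300)
        raw_r = np.corrcoef(ordered["protein_log2"], truth)[0, 1]
        prof_r = np.corrcoef(res.profile["profile_log2"], truth)[0, 1]
        assert prof_r > raw_r
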