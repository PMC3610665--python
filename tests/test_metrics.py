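"""Switch errors, sharing runs, best-match stats, error maps, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirrorphase as mp
from oracles import (best_match_lengths, imputed_error_recount, maximal_runs,
                     switch_count)


def _pair(h1, h2):
    return np.array([h1, h2], dtype=np.int8)


class TestSwitchErrors:
    def test_perfect_inference_zero(self, rng):
        t = rng.integers(0, 2, (2, 30)).astype(np.int8)
        assert mp.switch_errors(t, t).switch_count == 0

    def test_wholesale_swap_is_not_an_error(self, rng):
        t = rng.integers(0, 2, (2, 30)).astype(np.int8)
        assert mp.switch_errors(t, t[::-1]).switch_count == 0

    def test_flip_from_site_three_onward(self):
        """5 het sites; orientation flipped from the 3rd on -> 1 switch;
        flipped only at the 3rd -> 2 switches."""
        t = _pair([0, 0, 0, 0, 0], [1, 1, 1, 1, 1])
        tail_flip = _pair([0, 0, 1, 1, 1], [1, 1, 0, 0, 0])
        point_flip = _pair([0, 0, 1, 0, 0], [1, 1, 0, 1, 1])
        assert mp.switch_errors(t, tail_flip).switch_count == 1
        assert mp.switch_errors(t, point_flip).switch_count == 2
        rep = mp.switch_errors(t, tail_flip)
        np.testing.assert_array_equal(np.nonzero(rep.per_marker)[0], [2])

    def test_genotype_mismatch_sites_skipped(self):
        t = _pair([0, 0, 0, 0], [1, 1, 1, 1])
        f = _pair([0, 1, 0, 0], [1, 1, 1, 1])  # dosage 2 at site 1 vs true 1
        rep = mp.switch_errors(t, f)
        assert rep.skipped_sites == 1
        assert rep.switch_count == 0

    def test_scoreable_restriction(self):
        t = _pair([0, 0, 0, 0, 0], [1, 1, 1, 1, 1])
        f = _pair([0, 1, 0, 1, 0], [1, 0, 1, 0, 1])
        assert mp.switch_errors(t, f).switch_count == 4
        keep = np.array([True, False, True, False, True])
        assert mp.switch_errors(t, f, keep).switch_count == 0

    def test_matches_oracle_and_swap_invariance(self, rng):
        for _ in range(50):
            m = int(rng.integers(5, 40))
            t = rng.integers(0, 2, (2, m)).astype(np.int8)
            f = rng.integers(0, 2, (2, m)).astype(np.int8)
            expected = switch_count(t, f)
            assert mp.switch_errors(t, f).switch_count == expected
            assert mp.switch_errors(t[::-1], f).switch_count == expected
            assert mp.switch_errors(t, f[::-1]).switch_count == expected


class TestImputedAlleleErrors:
    def test_perfect_zero_and_opposite_homozygote_two(self):
        truth = np.array([[0, 1], [2, 0]], dtype=np.int8)
        assert mp.imputed_allele_errors(truth, truth.copy()) == 0
        calls = truth.copy()
        calls[1, 0] = 0  # truth 2 called 0: both alleles wrong
        assert mp.imputed_allele_errors(truth, calls) == 2

    def test_matches_recount_oracle(self, rng):
        truth = rng.integers(0, 3, (6, 25)).astype(np.int8)
        calls = rng.integers(0, 3, (6, 25)).astype(np.int8)
        assert mp.imputed_allele_errors(truth, calls) == \
            imputed_error_recount(truth, calls)


class TestSharingRuns:
    def test_twins_single_full_run(self):
        g = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        runs = mp.sharing_runs(g, g, "double")
        assert len(runs) == 1 and (runs[0].start, runs[0].end) == (0, 5)

    def test_opposing_homozygotes_break_single_run(self):
        ga = np.array([1, 0, 1, 1], dtype=np.int8)
        gb = np.array([1, 2, 1, 1], dtype=np.int8)
        runs = mp.sharing_runs(ga, gb, "single")
        assert [(r.start, r.end) for r in runs] == [(0, 1), (2, 4)]

    def test_double_runs_nested_in_single_runs(self, rng):
        ga = rng.integers(0, 3, 100).astype(np.int8)
        gb = rng.integers(0, 3, 100).astype(np.int8)
        singles = mp.sharing_runs(ga, gb, "single")
        for d in mp.sharing_runs(ga, gb, "double"):
            assert any(s.start <= d.start and d.end <= s.end for s in singles)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(2, 60))
        ga = r.integers(-1, 3, m).astype(np.int8)
        gb = r.integers(-1, 3, m).astype(np.int8)
        for kind in ("double", "single"):
            for strict in (True, False):
                got = [(x.start, x.end)
                       for x in mp.sharing_runs(ga, gb, kind,
                                                missing_matches=not strict)]
                assert got == maximal_runs(ga, gb, kind,
                                           missing_matches=not strict)


class TestBestMatchStats:
    def test_twins_cohort_all_full_length(self):
        spec = mp.ScenarioSpec(name="twins_all", n_parents=4, n_markers=30,
                               seed=1)
        truth = mp.build_scenario(spec)
        table, cohort = mp.best_match_stats(truth.genotypes, "double")
        assert cohort["longest_run"] == 30
        assert (table["max_best_match"] == 30).all()
        assert (table["mean_best_match"] == 30).all()

    def test_run_free_cohort_all_zero(self):
        d = np.array([[0, 2, 0], [2, 0, 2]], dtype=np.int8)
        table, cohort = mp.best_match_stats(d, "double")
        assert cohort["mean_best_match"] == 0
        assert cohort["longest_run"] == 0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(5, 100))
            d = rng.integers(0, 3, (n, m)).astype(np.int8)
            for kind in ("double", "single"):
                table, cohort = mp.best_match_stats(d, kind)
                best = best_match_lengths(d, kind)
                np.testing.assert_allclose(table["mean_best_match"],
                                           best.mean(axis=1))
                np.testing.assert_array_equal(table["max_best_match"],
                                              best.max(axis=1))
                assert cohort["mean_best_match"] == pytest.approx(best.mean())


class TestErrorMap:
    def _report(self, per_marker):
        arr = np.asarray(per_marker, dtype=bool)
        return mp.SwitchErrorReport(int(arr.sum()), arr, 0, int(arr.size))

    def test_rates_are_individual_fractions(self):
        reps = [self._report([0, 1, 0]), self._report([0, 1, 1]),
                self._report([0, 0, 0])]
        df = mp.per_marker_error_map({"m": reps})
        np.testing.assert_allclose(df["m"], [0, 2 / 3, 1 / 3])

    def test_no_switches_all_zero(self):
        df = mp.per_marker_error_map({"m": [self._report([0] * 5)] * 4})
        assert (df["m"] == 0).all()

    def test_block_lengths_shared_threshold(self):
        blocky = np.array([0.0, 0.5, 0.5, 0.5, 0.0, 0.0])
        scattered = np.array([0.0, 0.5, 0.0, 0.5, 0.0, 0.5])
        df = pd.DataFrame({"blocky": blocky, "scattered": scattered})
        lengths = mp.error_map_block_lengths(df)
        assert lengths["blocky"] == 3
        assert lengths["scattered"] == 1

    def test_longest_above_median_run(self):
        assert mp.longest_above_median_run(np.zeros(10)) == 0
        assert mp.longest_above_median_run(
            np.array([0, 0, 1, 1, 1, 0, 1, 0, 0, 0.0])) == 3


class TestCrossval:
    def test_flip_counts_reported_per_window(self):
        spec = mp.ScenarioSpec(name="parents_only", n_parents=10, n_markers=80,
                               seed=3)
        truth = mp.build_scenario(spec)
        cfg = mp.PhasingConfig(n_iterations=4, seed=5)
        flips = mp.crossval_flip_rate(truth.genotypes, cfg, k_subsets=2,
                                      holdout_fraction=0.2, window=20)
        assert {"individual", "window_start", "flips"} <= set(flips.columns)
        assert (flips["flips"] >= 0).all()
        assert flips["window_start"].max() < 80

    def test_duplicated_individuals_accumulate_more_flips(self):
        """A genotype-duplicated pair phases unstably across subset runs in
        original mode: its flip count exceeds the cohort median."""
        spec = mp.ScenarioSpec(name="parents_only", n_parents=12, n_markers=100,
                               seed=8)
        truth = mp.build_scenario(spec)
        d = truth.genotypes.dosage.copy()
        d[1] = d[0]  # individual 1 becomes individual 0's genotype twin
        genotypes = mp.GenotypeMatrix(dosage=d)
        cfg = mp.PhasingConfig(n_iterations=8, mode="original", seed=1)
        flips = mp.crossval_flip_rate(genotypes, cfg, k_subsets=3,
                                      holdout_fraction=0.25, window=25, seed=2)
        per_ind = flips.groupby("individual")["flips"].sum()
        dup = per_ind.reindex([0, 1]).fillna(0).mean()
        others = per_ind.drop([0, 1], errors="ignore")
        assert dup > others.median()

    def test_too_small_cohort_rejected(self):
        g = mp.GenotypeMatrix(dosage=np.zeros((2, 10), dtype=np.int8))
        with pytest.raises(mp.ConfigurationError):
            mp.crossval_flip_rate(g, mp.PhasingConfig(n_iterations=1),
                                  k_subsets=2, holdout_fraction=0.5)
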