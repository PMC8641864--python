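import numpy as np
import pandas as pd
import pytest

import pinglab as pl
from pinglab.decoding import DecodingTimecourse, ShuffleNull
from pinglab.inference import (
    bootstrap_ci,
    median_split_cv,
    randomization_test,
    subsample_grid,
    window_test,
)


def _dt(strength, time=None):
    strength = np.atleast_2d(strength)
    if time is None:
        time = np.linspace(0, 1, strength.shape[1])
    return DecodingTimecourse(strength, time, list(range(len(strength))), 8)


class TestWindowTest:
    def test_all_zero_strengths_give_chance(self):
        t, p = window_test(_dt(np.zeros((10, 20))), (0.2, 0.8))
        assert (t, p) == (0.0, 0.5)

    def test_strong_effect_highly_significant(self, rng):
        vals = rng.normal(0.5, 0.1, size=(30, 20))
        t, p = window_test(_dt(vals), (0.0, 1.0))
        assert p < 1e-6

    def test_null_calibration_at_5_percent(self, rng):
        rejections = 0
        for _ in range(1000):
            vals = rng.standard_normal((12, 5))
            _, p = window_test(_dt(vals), (0.0, 1.0))
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_pooled_trials_mode_requires_and_uses_trials(self, rng):
        dt = _dt(np.zeros((2, 10)))
        with pytest.raises(ValueError, match="trial_strengths"):
            window_test(dt, (0.2, 0.8), pool="pooled-trials")
        trials = {0: rng.normal(0.4, 0.1, (50, 10)),
                  1: rng.normal(0.4, 0.1, (50, 10))}
        _, p = window_test(dt, (0.2, 0.8), pool="pooled-trials",
                           trial_strengths=trials)
        assert p < 1e-6


class TestSubsampleGrid:
    def _table(self, rng, n_sessions=4, n_trials=30, effect=0.0):
        rows = []
        for s in range(n_sessions):
            for v in rng.normal(effect, 1.0, n_trials):
                rows.append((f"s{s}", v))
        return pd.DataFrame(rows, columns=["session", "strength"])

    def test_full_grid_corner_reproduces_pooled_test(self, rng):
        tab = self._table(rng, effect=0.3)
        grid = subsample_grid(tab, [2, 4], [10, 30], n_resamples=20, seed=0)
        import scipy.stats
        pooled_p = scipy.stats.ttest_1samp(
            tab["strength"], 0, alternative="greater").pvalue
        assert grid.pvals[-1, -1] == pytest.approx(pooled_p, rel=1e-12)

    def test_power_grows_along_both_axes(self, rng):
        tab = self._table(rng, n_sessions=6, n_trials=60, effect=0.25)
        grid = subsample_grid(tab, [2, 4, 6], [10, 30, 60],
                              n_resamples=200, seed=1)
        # mean p decreases monotonically down each axis (in expectation)
        assert np.all(np.diff(grid.pvals, axis=0) <= 0)
        assert np.all(np.diff(grid.pvals, axis=1) <= 0)

    def test_requests_beyond_pool_rejected(self, rng):
        tab = self._table(rng)
        with pytest.raises(ValueError, match="more sessions"):
            subsample_grid(tab, [5], [10], 10, 0)
        with pytest.raises(ValueError, match="more trials"):
            subsample_grid(tab, [2], [31], 10, 0)

    def test_null_mean_p_near_half(self, rng):
        tab = self._table(rng, n_sessions=6, n_trials=40, effect=0.0)
        grid = subsample_grid(tab, [4], [20], n_resamples=400, seed=2)
        assert abs(grid.pvals[0, 0] - 0.5) < 0.1


class TestBootstrapCI:
    def test_constant_input_degenerate_interval(self):
        sem, lo, hi = bootstrap_ci(np.full(10, 3.0), n_boot=200, seed=0)
        assert sem == 0 and lo == 3.0 and hi == 3.0

    def test_clear_effect_excludes_zero(self, rng):
        x = rng.normal(1.0, 0.1, 30)
        sem, lo, hi = bootstrap_ci(x, n_boot=5000, seed=0)
        assert lo > 0
        # bootstrap SEM close to the analytic SEM
        assert sem == pytest.approx(x.std(ddof=1) / np.sqrt(30), rel=0.15)

    def test_nominal_coverage(self, rng):
        covered = 0
        n_runs = 600
        for _ in range(n_runs):
            x = rng.normal(0.7, 1.0, 25)
            _, lo, hi = bootstrap_ci(x, n_boot=400,
                                     seed=int(rng.integers(2**31)))
            covered += lo <= 0.7 <= hi
        assert 0.91 <= covered / n_runs <= 0.975

    def test_small_n_boot_warns(self, rng):
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_ci(rng.standard_normal(5), n_boot=50, seed=0)


class TestRandomizationTest:
    def _pair(self, obs_level, null_draws, time=None):
        time = np.linspace(0, 1, 10) if time is None else time
        dt = _dt(np.full((3, 10), obs_level), time)
        null = ShuffleNull(null_draws, time, seed=0)
        return dt, null

    def test_observed_at_null_median_gives_half(self, rng):
        null = rng.standard_normal((999, 10))
        med = np.median(null.mean(axis=1))
        dt, nl = self._pair(med, null)
        assert randomization_test(dt, nl, (0.0, 1.0)) == pytest.approx(0.5, abs=0.05)

    def test_add_one_rule_floor(self, rng):
        null = rng.standard_normal((999, 10))
        dt, nl = self._pair(1e6, null)
        assert randomization_test(dt, nl, (0.0, 1.0)) == pytest.approx(1 / 1000)

    def test_invariant_under_monotone_rescaling(self, rng):
        null = rng.standard_normal((200, 10))
        dt, nl = self._pair(0.8, null)
        p1 = randomization_test(dt, nl, (0.0, 1.0))
        f = lambda x: np.exp(3 * x) - 1  # strictly increasing
        dt2 = _dt(f(dt.strength), dt.time)
        nl2 = ShuffleNull(f(null), nl.time, 0)
        # window means commute with f only per-sample; use 1-sample window
        p2 = randomization_test(
            _dt(f(dt.strength[:, :1]), dt.time[:1]),
            ShuffleNull(f(null[:, :1]), nl.time[:1], 0), (0.0, 0.01))
        p1s = randomization_test(
            _dt(dt.strength[:, :1], dt.time[:1]),
            ShuffleNull(null[:, :1], nl.time[:1], 0), (0.0, 0.01))
        assert p2 == p1s

    def test_time_axis_mismatch_rejected(self, rng):
        dt, nl = self._pair(0.0, rng.standard_normal((99, 10)))
        nl2 = ShuffleNull(nl.strengths, nl.time + 0.5, 0)
        with pytest.raises(ValueError, match="time axes"):
            randomization_test(dt, nl2, (0.0, 1.0))


class TestMedianSplit:
    def _acc(self, rng, n_sessions=6, n_trials=40, n_times=8, means=None):
        means = means if means is not None else np.zeros(n_sessions)
        return {f"s{i}": rng.standard_normal((n_trials, n_times)) + means[i]
                for i in range(n_sessions)}

    def test_no_spurious_selection_on_exchangeable_null(self, rng):
        # identical null sessions: the held-out high-group mean beats the
        # shuffle predictor in about half the split-folds
        time = np.linspace(0, 1, 8)
        acc = self._acc(rng)
        shuffles = [self._acc(rng) for _ in range(40)]
        res = median_split_cv(acc, time, split_window=(0.2, 0.6),
                              n_splitfolds=400, seed=0,
                              shuffle_trial_acc=shuffles,
                              n_predictor_folds=50)
        frac = res.significant_fraction.mean()
        assert 0.40 <= frac <= 0.60

    def test_planted_sessions_recovered_and_significant(self, rng):
        time = np.linspace(0, 1, 8)
        means = np.array([0.8, 0.8, 0.8, 0.0, 0.0, 0.0])
        acc = self._acc(rng, means=means)
        shuffles = [self._acc(rng) for _ in range(40)]
        res = median_split_cv(acc, time, split_window=(0.2, 0.6),
                              n_splitfolds=400, seed=0,
                              shuffle_trial_acc=shuffles,
                              n_predictor_folds=50)
        planted = {"s0", "s1", "s2"}
        enrich = np.mean([set(h) == planted for h in res.high_sessions])
        assert enrich > 0.9
        assert np.all(res.significant_fraction >= 0.95)

    def test_single_fold_reproducible_and_validation(self, rng):
        time = np.linspace(0, 1, 4)
        acc = self._acc(rng, n_sessions=5, n_times=4)
        r1 = median_split_cv(acc, time, (0.0, 1.0), n_splitfolds=1, seed=3)
        r2 = median_split_cv(acc, time, (0.0, 1.0), n_splitfolds=1, seed=3)
        assert np.array_equal(r1.heldout_high, r2.heldout_high)
        # odd session count: high group gets the extra session
        assert len(r1.high_sessions[0]) == 3
        with pytest.raises(ValueError, match="at least 4 sessions"):
            median_split_cv({"a": acc["s0"], "b": acc["s1"]}, time, (0, 1))
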