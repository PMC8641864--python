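"""Statistical-power and significance machinery.

Windowed one-sided tests on decoding strength, trial/session subsampling
grids, bootstrap CIs, randomization (permutation) tests against a shuffle
null, and the cross-validated median split with its shuffle predictor.
One-sided tests are used throughout because negative decoding strengths
are not expected, and a one-sided test is the conservative choice when
arguing for a *lack* of decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .decoding import DecodingTimecourse, ShuffleNull

__all__ = [
    "SubsampleGrid",
    "MedianSplitResult",
    "window_test",
    "subsample_grid",
    "bootstrap_ci",
    "randomization_test",
    "median_split_cv",
]


def _one_sided_t(values: np.ndarray) -> tuple[float, float]:
    """One-sample, one-sided t test of mean > 0, robust to zero variance."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or values.std(ddof=1) == 0:
        m = values.mean()
        if m == 0:
            return 0.0, 0.5
        return (np.inf if m > 0 else -np.inf), (0.0 if m > 0 else 1.0)
    t, p = scipy.stats.ttest_1samp(values, 0.0, alternative="greater")
    return float(t), float(p)


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    start, stop = window
    if stop <= start:
        raise ValueError(f"empty window {window}")
    m = (time >= start - 1e-12) & (time <= stop + 1e-12)
    if not m.any():
        raise ValueError(f"window {window} outside time axis")
    return m


def window_test(
    dt: DecodingTimecourse,
    window: tuple[float, float],
    pool: str = "sessions",
    trial_strengths=None,
) -> tuple[float, float]:
    """One-sided t test of window-averaged decoding strength against 0.

    ``pool="sessions"`` averages the strength over the window per session
    and tests across sessions; ``pool="pooled-trials"`` tests across
    single trials pooled over sessions (requires ``trial_strengths``, a
    mapping session -> (n_trials, n_times) as returned by
    :func:`pinglab.decoding.decode_single_trials`).
    """
    m = _window_mask(dt.time, window)
    if pool == "sessions":
        vals = dt.strength[:, m].mean(axis=1)
    elif pool == "pooled-trials":
        if trial_strengths is None:
            raise ValueError("pooled-trials mode requires trial_strengths")
        vals = np.concatenate(
            [np.asarray(s)[:, m].mean(axis=1) for s in trial_strengths.values()]
        )
    else:
        raise ValueError("pool must be 'sessions' or 'pooled-trials'")
    return _one_sided_t(vals)


@dataclass
class SubsampleGrid:
    """Mean strength and one-sided p per (n_sessions, n_trials) cell."""

    n_sessions_axis: np.ndarray
    n_trials_axis: np.ndarray
    stat: np.ndarray  # (len(sessions_axis), len(trials_axis))
    pvals: np.ndarray
    n_resamples: int
    seed: int


def subsample_grid(
    trial_table: pd.DataFrame,
    n_sessions_axis,
    n_trials_axis,
    n_resamples: int = 5000,
    seed: int = 0,
    value_col: str = "strength",
    session_col: str = "session",
) -> SubsampleGrid:
    """Decoding strength as a function of session and trial count.

    ``trial_table`` holds one row per trial with its window-averaged
    decoding strength.  For each grid cell, ``n_resamples`` draws pick
    that many sessions and, within each, that many trials — both without
    repetition — and the cell records the mean strength and the mean
    one-sided t-test p over resamples.  The full-data corner therefore
    reproduces the pooled-trials window test exactly.
    """
    rng = np.random.default_rng(seed)
    sessions = np.asarray(sorted(trial_table[session_col].unique()))
    by_sess = {
        s: trial_table.loc[trial_table[session_col] == s, value_col].to_numpy()
        for s in sessions
    }
    n_sessions_axis = np.asarray(n_sessions_axis, dtype=int)
    n_trials_axis = np.asarray(n_trials_axis, dtype=int)
    if n_sessions_axis.max() > sessions.size:
        raise ValueError("requested more sessions than available")
    min_trials = min(len(v) for v in by_sess.values())
    if n_trials_axis.max() > min_trials:
        raise ValueError("requested more trials than the smallest session has")

    stat = np.empty((n_sessions_axis.size, n_trials_axis.size))
    pvals = np.empty_like(stat)
    for i, ns in enumerate(n_sessions_axis):
        for j, nt in enumerate(n_trials_axis):
            exhaustive = ns == sessions.size and all(
                nt == len(by_sess[s]) for s in sessions
            )
            reps = 1 if exhaustive else n_resamples
            ms = np.empty(reps)
            ps = np.empty(reps)
            for r in range(reps):
                chosen = rng.choice(sessions, size=ns, replace=False)
                vals = np.concatenate(
                    [rng.choice(by_sess[s], size=nt, replace=False) for s in chosen]
                )
                ms[r] = vals.mean()
                ps[r] = _one_sided_t(vals)[1]
            stat[i, j] = ms.mean()
            pvals[i, j] = ps.mean()
    return SubsampleGrid(n_sessions_axis, n_trials_axis, stat, pvals,
                         n_resamples, seed)


def bootstrap_ci(
    x: np.ndarray,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
):
    """Bootstrap SEM and percentile CI of the mean over the first axis.

    ``x`` is (n_units,) or (n_units, n_times); units (sessions) are
    resampled with replacement.  Returns ``(sem, ci_low, ci_high)`` with
    the same trailing shape as ``x``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units to bootstrap")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap estimates")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = x[idx].mean(axis=1)  # (n_boot, ...)
    sem = means.std(axis=0, ddof=1)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(means, alpha, axis=0)
    hi = np.quantile(means, 1.0 - alpha, axis=0)
    return sem, lo, hi


def randomization_test(
    dt: DecodingTimecourse,
    null: ShuffleNull,
    window: tuple[float, float],
) -> float:
    """One-sided permutation p for window-mean strength vs the shuffle null.

    Uses the add-one convention ``p = (1 + #{null >= observed}) /
    (1 + n_shuffles)`` so p is never exactly 0.
    """
    if dt.time.shape != null.time.shape or not np.allclose(dt.time, null.time):
        raise ValueError("observed and null timecourses use different time axes")
    m = _window_mask(dt.time, window)
    obs = dt.strength[:, m].mean()
    null_means = null.strengths[:, m].mean(axis=1)
    return float((1 + np.sum(null_means >= obs)) / (1 + null.n_shuffles))


# ---------------------------------------------------------------------------
# cross-validated median split

@dataclass
class MedianSplitResult:
    """Outcome of the cross-validated session median split."""

    time: np.ndarray
    heldout_high: np.ndarray   # (n_splitfolds, n_times)
    heldout_low: np.ndarray
    high_sessions: list        # per fold, list of session ids ranked high
    shuffle_predictor: np.ndarray | None  # (n_times,) mean null high-group strength
    significant_fraction: np.ndarray | None  # per time, fraction folds > predictor
    n_splitfolds: int
    split_window: tuple[float, float]
    seed: int
    criterion: float = 0.95

    @property
    def significant(self):
        """Timepoints where >= ``criterion`` of split-folds beat the predictor."""
        if self.significant_fraction is None:
            return None
        return self.significant_fraction >= self.criterion


def _split_halves(rng, n_trials, labels=None):
    """Random half split of trial indices, stratified by label if given."""
    idx = np.arange(n_trials)
    if labels is None:
        perm = rng.permutation(idx)
        return perm[: n_trials // 2], perm[n_trials // 2:]
    h1, h2 = [], []
    for lab in np.unique(labels):
        sub = rng.permutation(idx[labels == lab])
        h1.append(sub[: len(sub) // 2])
        h2.append(sub[len(sub) // 2:])
    return np.concatenate(h1), np.concatenate(h2)


def _median_split_folds(
    trial_acc, time, split_window, n_splitfolds, rng, labels=None
):
    """Core split-fold machinery over precomputed per-trial accuracies.

    ``trial_acc``: mapping session -> (n_trials, n_times).  Returns
    (heldout_high, heldout_low, high_sessions) per fold; the high group
    gets the extra session when the session count is odd.
    """
    sessions = list(trial_acc)
    m = _window_mask(time, split_window)
    n_half_high = (len(sessions) + 1) // 2
    hh = np.empty((n_splitfolds, time.size))
    hl = np.empty((n_splitfolds, time.size))
    high_ids = []
    for f in range(n_splitfolds):
        rank_score = np.empty(len(sessions))
        heldout = np.empty((len(sessions), time.size))
        for s_i, sid in enumerate(sessions):
            acc = np.asarray(trial_acc[sid])
            lab = None if labels is None else np.asarray(labels[sid])
            i1, i2 = _split_halves(rng, acc.shape[0], lab)
            rank_score[s_i] = acc[i1][:, m].mean()
            heldout[s_i] = acc[i2].mean(axis=0)
        order = np.argsort(-rank_score, kind="stable")
        top = order[:n_half_high]
        bot = order[n_half_high:]
        hh[f] = heldout[top].mean(axis=0)
        hl[f] = heldout[bot].mean(axis=0)
        high_ids.append([sessions[i] for i in top])
    return hh, hl, high_ids


def median_split_cv(
    trial_acc,
    time: np.ndarray,
    split_window: tuple[float, float] = (0.25, 0.45),
    n_splitfolds: int = 2000,
    seed: int = 0,
    labels=None,
    shuffle_trial_acc=None,
    n_predictor_folds: int = 200,
    criterion: float = 0.95,
) -> MedianSplitResult:
    """Cross-validated median split of sessions by decodability.

    Per split-fold, each session's single-trial decoding accuracies are
    randomly halved (stratified by orientation when ``labels`` is given);
    the first halves rank the sessions by mean accuracy inside
    ``split_window`` and define the high/low median split, the second
    halves supply the held-out accuracy of each group.  Selection is thus
    never evaluated on the trials that produced it.

    ``shuffle_trial_acc`` — a sequence of label-shuffled replicates of
    ``trial_acc`` (one per shuffled decoder) — yields the shuffle
    predictor: each shuffled decoder is run through the same procedure
    with ``n_predictor_folds`` split-folds and the high-group held-out
    strengths are averaged.  The high group's strength at a timepoint is
    declared significant when at least ``criterion`` (default 95%) of the
    split-folds exceed the predictor.
    """
    sessions = list(trial_acc)
    if len(sessions) < 4:
        raise ValueError("need at least 4 sessions for a median split")
    for sid in sessions:
        if np.asarray(trial_acc[sid]).shape[0] < 2:
            raise ValueError(f"session {sid!r} has fewer than 2 trials")
    time = np.asarray(time, dtype=float)
    rng = np.random.default_rng(seed)
    hh, hl, high_ids = _median_split_folds(
        trial_acc, time, split_window, n_splitfolds, rng, labels
    )
    predictor = None
    sig_frac = None
    if shuffle_trial_acc is not None:
        acc_null = np.zeros(time.size)
        for shuf in shuffle_trial_acc:
            shh, _, _ = _median_split_folds(
                shuf, time, split_window, n_predictor_folds, rng, labels
            )
            acc_null += shh.mean(axis=0)
        predictor = acc_null / len(shuffle_trial_acc)
        sig_frac = (hh > predictor[None, :]).mean(axis=0)
    return MedianSplitResult(
        time, hh, hl, high_ids, predictor, sig_frac,
        n_splitfolds, tuple(split_window), seed, criterion,
    )
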