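"""Across-trial variance analyses.

The across-trial variance of the raw voltage (trials x sensors x time) is
computed per session, linearly detrended per sensor to remove slow drifts
(e.g. moving electrodes), averaged over sensors, and only then averaged
across sessions — the per-session ordering matters because pooled
variance absorbs between-session mean differences.  Δvar expresses the
variance as percent change from a pre-impulse baseline:
``Δvar = (var − b) / b * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .containers import EpochSet
from .preprocess import detrend_linear

__all__ = [
    "VarianceTimecourse",
    "across_trial_variance",
    "delta_var",
    "variance_by_decoding_split",
    "exclude_outlier_sessions",
]


@dataclass
class VarianceTimecourse:
    """Sensor-averaged across-trial variance per session."""

    var: np.ndarray       # (n_sessions, n_times)
    time: np.ndarray
    sessions: list
    detrended: bool = True

    def __post_init__(self):
        self.var = np.atleast_2d(np.asarray(self.var, dtype=float))
        self.time = np.asarray(self.time, dtype=float)

    def mean(self) -> np.ndarray:
        """Session-averaged variance timecourse."""
        return self.var.mean(axis=0)


def _session_variance(data: np.ndarray, detrend: bool) -> np.ndarray:
    """Across-trial variance, per-sensor detrended, sensor-averaged."""
    if data.shape[0] < 2:
        raise ValueError("need at least 2 trials to compute across-trial variance")
    v = data.var(axis=0, ddof=1)  # (channels, times)
    if detrend:
        v = detrend_linear(v, axis=-1)
    return v.mean(axis=0)


def across_trial_variance(e: EpochSet, detrend: bool = True) -> VarianceTimecourse:
    """Across-trial voltage variance, computed per session.

    Per session: variance over trials at each sensor and timepoint, the
    per-sensor variance timecourses linearly detrended, then averaged
    over sensors.  Note that detrending centres each sensor's variance
    around its own trend, so detrended values can dip below zero.
    """
    rows, sessions = [], []
    for sid, sess in e.sessions():
        rows.append(_session_variance(sess.data, detrend))
        sessions.append(sid)
    return VarianceTimecourse(np.vstack(rows), e.times, sessions, detrend)


def delta_var(
    v: VarianceTimecourse, baseline_window: tuple[float, float]
) -> np.ndarray:
    """Percent variance change relative to a baseline window, per session.

    ``Δvar = (var − b) / b * 100`` with ``b`` the session's mean variance
    inside ``baseline_window``.  Being a percent change, Δvar is
    invariant under global rescaling of the voltages.
    """
    start, stop = baseline_window
    m = (v.time >= start - 1e-12) & (v.time <= stop + 1e-12)
    if not m.any():
        raise ValueError(f"baseline window {baseline_window} outside time axis")
    b = v.var[:, m].mean(axis=1, keepdims=True)
    if np.any(b <= 0):
        bad = [v.sessions[i] for i in np.nonzero(b[:, 0] <= 0)[0]]
        raise ValueError(
            f"non-positive baseline variance for sessions {bad}; "
            "detrending may have centred the variance — use a raw "
            "(detrend=False) variance or a different baseline window"
        )
    return (v.var - b) / b * 100.0


def variance_by_decoding_split(
    e: EpochSet,
    trial_strengths: np.ndarray,
    t_ref: float,
    quantile: float = 0.5,
    detrend: bool = True,
    alpha: float = 0.005,
):
    """Variance difference between low- and high-decoding trials.

    Trials are split per session at the ``quantile`` of their decoding
    strength at ``t_ref`` (the time of maximal decodability); the
    across-trial variance timecourse is computed for each group and their
    difference (low − high) is tested across sessions with a two-sided t
    test per timepoint, flagged at ``p < alpha``.

    Returns ``(diff, tstat, pvals, significant)`` where ``diff`` is
    (n_sessions, n_times).
    """
    trial_strengths = np.asarray(trial_strengths, dtype=float)
    if trial_strengths.shape[0] != e.n_trials:
        raise ValueError("one strength per trial required")
    if trial_strengths.ndim == 2:
        i_ref = int(np.argmin(np.abs(e.times - t_ref)))
        strengths = trial_strengths[:, i_ref]
    else:
        strengths = trial_strengths
    diffs = []
    offset = 0
    for sid, sess in e.sessions():
        s = strengths[offset: offset + sess.n_trials]
        offset += sess.n_trials
        thr = np.quantile(s, quantile)
        low = s < thr
        high = ~low
        if low.sum() < 2 or high.sum() < 2:
            raise ValueError(
                f"degenerate decoding split in session {sid!r} "
                "(all strengths equal?)"
            )
        v_low = _session_variance(sess.data[low], detrend)
        v_high = _session_variance(sess.data[high], detrend)
        diffs.append(v_low - v_high)
    diff = np.vstack(diffs)
    if diff.shape[0] >= 2:
        tstat, pvals = scipy.stats.ttest_1samp(diff, 0.0, axis=0)
    else:
        tstat = np.full(diff.shape[1], np.nan)
        pvals = np.ones(diff.shape[1])
    return diff, np.asarray(tstat), np.asarray(pvals), np.asarray(pvals) < alpha


def exclude_outlier_sessions(
    v: VarianceTimecourse,
    impulse_time: float,
    criterion: float = 5.0,
):
    """Drop sessions with extreme variance at the impulse (artifact screen).

    A session is excluded when its variance at ``impulse_time`` exceeds
    ``median + criterion * MAD`` across sessions.  Returns the kept
    :class:`VarianceTimecourse` and a report dict listing excluded
    sessions with their values.
    """
    if v.var.shape[0] < 3:
        raise ValueError("need at least 3 sessions to screen for outliers")
    i = int(np.argmin(np.abs(v.time - impulse_time)))
    vals = v.var[:, i]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thr = med + criterion * mad
    keep = vals <= thr
    kept = VarianceTimecourse(
        v.var[keep], v.time,
        [s for s, k in zip(v.sessions, keep) if k], v.detrended,
    )
    report = {
        "threshold": float(thr),
        "median": float(med),
        "mad": float(mad),
        "excluded": [
            {"session": s, "value": float(x)}
            for s, x, k in zip(v.sessions, vals, keep) if not k
        ],
        "n_excluded": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    return kept, report
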