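"""Epoch-level signal conditioning.

Baselining and its reversal (epoch stitching), per-sensor linear
detrending, gaussian temporal smoothing, and Hilbert-based alpha-band
total power.  All operations preserve the :class:`~pinglab.containers.EpochSet`
container.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage
import scipy.signal

from .containers import EpochSet

__all__ = [
    "BaselineSpec",
    "BandSpec",
    "apply_baseline",
    "debaseline_stitch",
    "detrend_linear",
    "smooth_gaussian",
    "alpha_power",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline-correction window (seconds, epoch time axis)."""

    window: tuple[float, float]
    mode: str = "subtract-mean"

    def __post_init__(self):
        if self.window[0] >= self.window[1]:
            raise ValueError("baseline window start must precede end")
        if self.mode != "subtract-mean":
            raise ValueError(f"unknown baseline mode {self.mode!r}")


@dataclass(frozen=True)
class BandSpec:
    """Frequency band in Hz; default is the 8–12 Hz alpha band."""

    low: float = 8.0
    high: float = 12.0

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")


def apply_baseline(e: EpochSet, spec: BaselineSpec) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window.

    Idempotent: re-baselining with the same window is a no-op.
    """
    idx = e.time_indices(spec.window)
    base = e.data[:, :, idx].mean(axis=2, keepdims=True)
    return replace(e, data=e.data - base, trial_meta=e.trial_meta.copy())


def debaseline_stitch(epoch_a: EpochSet, epoch_b: EpochSet) -> EpochSet:
    """Revert per-epoch baselining by stitching consecutive epochs.

    ``epoch_b`` must follow ``epoch_a`` in time, either overlapping it or
    abutting it (next sample).  The trial-by-trial, channel-by-channel
    voltage offset between the two epochs — measured over the overlap, or
    at the junction samples if they merely abut — is added back to
    ``epoch_b``, which removes whatever constant each epoch's separate
    baselining subtracted.  The result is the concatenated continuous
    epoch on ``epoch_a``'s time axis.
    """
    if epoch_a.n_trials != epoch_b.n_trials or epoch_a.n_channels != epoch_b.n_channels:
        raise ValueError("epochs must share trial and channel dimensions")
    if epoch_a.srate != epoch_b.srate:
        raise ValueError("epochs must share the sampling rate")
    if epoch_b.n_samples == 0 or epoch_a.n_samples == 0:
        raise ValueError("cannot stitch a zero-length epoch")
    dt = 1.0 / epoch_a.srate
    end_a = epoch_a.t0 + (epoch_a.n_samples - 1) * dt
    # integer sample offset of b's first sample relative to a's first
    off = (epoch_b.t0 - epoch_a.t0) / dt
    off_i = int(round(off))
    if abs(off - off_i) > 1e-6:
        raise ValueError("epochs are not on a common sample grid")
    if off_i <= 0:
        raise ValueError("epoch_b must start after epoch_a")
    n_overlap = epoch_a.n_samples - off_i
    if n_overlap > 0:
        # offset = mean over the overlapping samples of (a - b)
        a_ov = epoch_a.data[:, :, off_i:]
        b_ov = epoch_b.data[:, :, :n_overlap]
        offset = (a_ov - b_ov).mean(axis=2, keepdims=True)
        tail = epoch_b.data[:, :, n_overlap:] + offset
    elif epoch_b.t0 - end_a <= 1.5 * dt:
        # abutment: junction-sample difference estimates the offset
        offset = (epoch_a.data[:, :, -1] - epoch_b.data[:, :, 0])[:, :, None]
        tail = epoch_b.data + offset
    else:
        raise ValueError("epochs neither overlap nor abut; cannot stitch")
    data = np.concatenate([epoch_a.data, tail], axis=2)
    return EpochSet(
        data, epoch_a.srate, epoch_a.t0, epoch_a.channel_labels,
        epoch_a.trial_meta.copy(),
    )


def detrend_linear(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares line along ``axis`` (per series)."""
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 2:
        raise ValueError("need at least 2 samples to detrend")
    return scipy.signal.detrend(x, axis=axis, type="linear")


def smooth_gaussian(e, sigma: float, srate: float | None = None):
    """Gaussian temporal smoothing (unit-area kernel, reflected edges).

    ``sigma`` is in seconds.  Accepts an :class:`EpochSet` (smooths the
    sample axis) or a bare array plus ``srate`` (smooths the last axis,
    e.g. a decoding-strength timecourse).  ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if isinstance(e, EpochSet):
        if sigma == 0:
            return e.copy()
        out = scipy.ndimage.gaussian_filter1d(
            e.data, sigma * e.srate, axis=-1, mode="reflect", truncate=8.0
        )
        return replace(e, data=out, trial_meta=e.trial_meta.copy())
    x = np.asarray(e, dtype=float)
    if sigma == 0:
        return x.copy()
    if srate is None:
        raise ValueError("srate required when smoothing a bare array")
    return scipy.ndimage.gaussian_filter1d(
        x, sigma * srate, axis=-1, mode="reflect", truncate=8.0
    )



def alpha_power(
    e: EpochSet, band: BandSpec = BandSpec(), numtaps: int | None = None
) -> EpochSet:
    """Band-limited total power via the analytic (Hilbert) signal.

    The data are band-passed with a zero-phase FIR filter (forward–
    backward), Hilbert transformed, and the squared complex magnitude is
    returned per trial, channel and sample.  For a unit-amplitude
    sinusoid inside the band the interior power is ~1.

    Edge samples within one filter half-width are distorted by the
    filter's startup transient; exclude roughly ``numtaps // 2`` samples
    at each end when asserting on values.
    """
    nyq = e.srate / 2.0
    if not (0 < band.low < band.high < nyq):
        raise ValueError(
            f"band ({band.low}, {band.high}) Hz invalid for srate {e.srate} Hz"
        )
    if numtaps is None:
        # ~2 cycles of the low edge, odd length
        numtaps = int(2 * e.srate / band.low) | 1
    numtaps = min(numtaps | 1, (e.n_samples - 1) // 3 * 2 + 1)
    taps = scipy.signal.firwin(
        numtaps, [band.low, band.high], pass_zero=False, fs=e.srate
    )
    filt = scipy.signal.filtfilt(taps, [1.0], e.data, axis=-1)
    analytic = scipy.signal.hilbert(filt, axis=-1)
    return replace(e, data=np.abs(analytic) ** 2, trial_meta=e.trial_meta.copy())
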