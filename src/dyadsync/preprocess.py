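"""Preprocessing of HbO recordings: edge trimming, detrending, and TDDR
motion-artifact correction.

Temporal Derivative Distribution Repair (TDDR) suppresses motion spikes
and baseline shifts by robustly re-weighting the temporal derivative of
the slow part of the signal: samples whose derivative is an outlier under
a Tukey-biweight robust fit are shrunk toward the robust mean before the
derivative is re-integrated.  The operation is parameter-free apart from
the standard robust-statistics constants, which are exposed for
inspection.

No band-pass filtering is applied here: frequency selection happens
after coherence is computed (the full frequency range feeds the wavelet
analysis; the frequency bands of interest are chosen statistically
downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as ssig

from .io import Recording

__all__ = ["TDDRParams", "trim_edges", "detrend", "tddr", "tddr_channel"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TDDRParams:
    """Constants of the TDDR robust re-weighting.

    tuning_constant:
        Tukey biweight cutoff c; residuals beyond c robust standard
        deviations get zero weight.  4.685 gives 95% Gaussian efficiency.
    mad_scale:
        1.4826, the factor making the median absolute deviation a
        consistent estimator of a Gaussian standard deviation.
    convergence_tol:
        Iteration stops when the largest weight change falls below this.
    split_freq_hz:
        The signal is split at this cutoff; the robust repair acts on the
        fast fluctuation component (where motion transients live), and
        the slow component below the cutoff passes through untouched.
    """

    tuning_constant: float = 4.685
    mad_scale: float = 1.4826
    convergence_tol: float = 1e-8
    max_iterations: int = 50
    split_freq_hz: float = 0.5

    def __post_init__(self):
        if self.tuning_constant <= 0 or self.convergence_tol <= 0:
            raise ValueError("tuning_constant and convergence_tol must be positive")


def trim_edges(recording: Recording, trim_s: float = 30.0) -> Recording:
    """Drop the first and last ``trim_s`` seconds of every channel
    (instrument settle-in and tear-down are unusable)."""
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    if trim_s == 0:
        return recording.copy()
    if recording.duration_s <= 2 * trim_s:
        raise ValueError(
            f"recording of {recording.duration_s:.1f} s too short to trim "
            f"{trim_s} s from each edge"
        )
    k = int(round(trim_s * recording.sampling_rate))
    out = recording.copy()
    out.data = out.data[:, k: out.data.shape[1] - k].copy()
    return out


def _fit_trend(y: np.ndarray, order: int) -> np.ndarray:
    t = np.arange(y.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, y, order)
    return np.polynomial.polynomial.polyval(t, coeffs)


def detrend(recording: Recording, order: int = 1) -> Recording:
    """Subtract a per-channel least-squares polynomial trend (linear by
    default); output channels have zero mean and zero fitted slope."""
    if recording.n_samples < order + 2:
        raise ValueError("too few samples to fit the trend")
    out = recording.copy()
    for i in range(out.n_channels):
        out.data[i] = out.data[i] - _fit_trend(out.data[i], order)
    return out


def tddr_channel(y: np.ndarray, rate: float,
                 params: TDDRParams = TDDRParams()) -> np.ndarray:
    """TDDR-correct one channel.

    The channel is linearly detrended first and the trend restored at the
    end, so constants and pure ramps pass through unchanged.  The
    detrended signal is split at ``split_freq_hz`` with a zero-phase
    Butterworth filter; the fast fluctuation part's first differences are
    iteratively re-weighted (Tukey biweight on MAD-standardized
    residuals), shrunk, re-integrated and recombined with the untouched
    slow part, so hemodynamic-band content is preserved while motion
    transients are repaired.

    A constant derivative (robust scale zero) means there is nothing to
    repair: all weights are 1 and the input is returned unchanged.
    """
    y = np.asarray(y, dtype=float)
    trend = _fit_trend(y, 1)
    x = y - trend

    fc = params.split_freq_hz * 2.0 / rate
    if fc < 1.0:
        b, a = ssig.butter(3, fc)
        low = ssig.filtfilt(b, a, x)
    else:
        low = np.zeros_like(x)
    fluct = x - low

    d = np.diff(fluct)
    w = np.ones_like(d)
    mu = 0.0
    for it in range(params.max_iterations):
        mu = np.sum(w * d) / np.sum(w)
        dev = np.abs(d - mu)
        sigma = params.mad_scale * np.median(dev)
        if sigma == 0.0:
            # constant derivative: nothing is an outlier
            return y.copy()
        r = dev / (sigma * params.tuning_constant)
        w_new = np.where(r < 1, (1 - r**2) ** 2, 0.0)
        delta = np.max(np.abs(w_new - w)) if it > 0 else np.inf
        w = w_new
        if delta < params.convergence_tol:
            break
    else:
        log.warning("TDDR did not converge in %d iterations; using last weights",
                    params.max_iterations)

    corrected = np.concatenate([[0.0], np.cumsum(w * (d - mu))])
    corrected -= corrected.mean()
    return corrected + low + trend


def tddr(recording: Recording, params: TDDRParams = TDDRParams()) -> Recording:
    """Apply TDDR motion correction to every channel of a recording."""
    out = recording.copy()
    for i in range(out.n_channels):
        out.data[i] = tddr_channel(out.data[i], out.sampling_rate, params)
    return out
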