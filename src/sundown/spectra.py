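"""Sliding-window EEG spectral analysis and rule-based sleep staging.

Spectral analysis runs an FFT over a 5 s window stepped by 2 s (frequency
resolution 0.2 Hz, Hann taper, one-sided density).  Staging applies the
classical criteria per 2-s bin: high EMG → Wake; otherwise a high
theta/delta ratio → REM; otherwise NREM (synchronized, delta-dominant EEG
with low EMG).  Features are z-scored over the record so the thresholds are
in SD units; an optional 3-bin majority filter smooths isolated bins.

State-averaged spectra are normalized so that mean power over 0.1–50 Hz is
1, then log2-transformed; band statistics are trapezoidal AUCs of the
normalized spectrum over the delta (0.1–4), theta (4–10), alpha (10–13),
beta (13.1–30) and gamma (30.1–50 Hz) ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from sundown.rhythms import Hypnogram

__all__ = [
    "EEGRecording",
    "Spectrogram",
    "NormalizedSpectrum",
    "BANDS",
    "sliding_spectrogram",
    "bin_emg_rms",
    "score_states",
    "normalize_spectrum",
    "band_auc",
    "band_auc_table",
]

#: Canonical frequency bands (Hz).  Beta starts at 13.1 and gamma at 30.1;
#: grid points in the printed gaps belong to neither band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 10.0),
    "alpha": (10.0, 13.0),
    "beta": (13.1, 30.0),
    "gamma": (30.1, 50.0),
}

NORM_RANGE = (0.1, 50.0)


@dataclass
class EEGRecording:
    """Paired EEG/EMG traces (µV) at a common sampling rate."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_zt: float = 0.0

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("EEG and EMG must have equal length")
        if self.fs < 100:
            raise ValueError("sampling rate must be at least 100 Hz")

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.fs


@dataclass
class Spectrogram:
    """One-sided power spectral density per sliding window."""

    freqs: np.ndarray            # Hz
    times: np.ndarray            # window start time, s
    power: np.ndarray            # (n_freqs, n_bins), µV²/Hz
    window_s: float
    step_s: float

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


@dataclass
class NormalizedSpectrum:
    """State-averaged spectrum normalized to mean 1 over 0.1–50 Hz, log2."""

    freqs: np.ndarray
    log2_power: np.ndarray
    normalized_power: np.ndarray = field(repr=False)


def sliding_spectrogram(rec: EEGRecording, window_s: float = 5.0, step_s: float = 2.0) -> Spectrogram:
    """Hann-tapered periodograms over a sliding window.

    Bin count is floor((T − window)/step) + 1; frequency resolution is
    1/window (0.2 Hz at the 5 s default).
    """
    nper = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if len(rec.eeg) < nper:
        raise ValueError("record shorter than one window")
    freqs, times, Sxx = signal.spectrogram(
        rec.eeg, fs=rec.fs, window="hann", nperseg=nper,
        noverlap=nper - step, scaling="density", mode="psd", detrend=False,
    )
    # scipy reports window centers; convert to window starts
    times = times - window_s / 2.0
    return Spectrogram(freqs=freqs, times=times, power=Sxx,
                       window_s=window_s, step_s=step_s)


def bin_emg_rms(rec: EEGRecording, window_s: float = 5.0, step_s: float = 2.0) -> np.ndarray:
    """EMG RMS over the same sliding windows as the spectrogram."""
    nper = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    n_bins = (len(rec.emg) - nper) // step + 1
    out = np.empty(n_bins)
    for i in range(n_bins):
        seg = rec.emg[i * step : i * step + nper]
        out[i] = np.sqrt(np.mean(seg**2))
    return out


def _band_power(spec: Spectrogram, lo: float, hi: float) -> np.ndarray:
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    return spec.power[m].sum(axis=0)


def score_states(
    spec: Spectrogram,
    emg_rms: np.ndarray,
    emg_z: float = 0.5,
    theta_delta_z: float = 1.0,
    smooth: bool = True,
    start_zt: float = 0.0,
) -> Hypnogram:
    """Rule-based Wake/NREM/REM staging of spectrogram bins.

    Per bin, delta power, the theta/delta ratio and EMG RMS are z-scored
    over the record.  EMG above ``emg_z`` SD → Wake; else theta/delta above
    ``theta_delta_z`` SD → REM; else NREM.  ``smooth`` applies a 3-bin
    majority filter to suppress single-bin flickers.  Epoch duration of the
    returned hypnogram is the spectrogram step.
    """
    if len(emg_rms) != spec.n_bins:
        raise ValueError("EMG bins misaligned with spectrogram bins")
    delta = _band_power(spec, *BANDS["delta"])
    theta = _band_power(spec, *BANDS["theta"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)

    def z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z_emg, z_ratio = z(np.asarray(emg_rms, dtype=float)), z(ratio)
    states = np.where(z_emg > emg_z, "Wake",
                      np.where(z_ratio > theta_delta_z, "REM", "NREM")).astype(object)
    if smooth and len(states) >= 3:
        smoothed = states.copy()
        for i in range(1, len(states) - 1):
            trio = states[i - 1 : i + 2]
            vals, counts = np.unique(trio.astype(str), return_counts=True)
            if counts.max() >= 2:
                smoothed[i] = vals[np.argmax(counts)]
        states = smoothed
    return Hypnogram(states=states, epoch_s=spec.step_s, start_zt=start_zt)


def normalize_spectrum(spec: Spectrogram, state_mask: np.ndarray | None = None) -> NormalizedSpectrum:
    """Average masked bins, normalize to mean 1 over 0.1–50 Hz, log2.

    ``state_mask`` selects the bins to average (e.g. all NREM-scored bins);
    by default every bin contributes.  The pre-log normalized power has
    mean exactly 1 over the 0.1–50 Hz grid points, making the spectrum
    scale-invariant.
    """
    if state_mask is None:
        state_mask = np.ones(spec.n_bins, dtype=bool)
    state_mask = np.asarray(state_mask, dtype=bool)
    if state_mask.shape != (spec.n_bins,):
        raise ValueError("state mask misaligned with spectrogram bins")
    if not state_mask.any():
        raise ValueError("state mask selects no bins")
    mean_power = spec.power[:, state_mask].mean(axis=1)
    in_range = (spec.freqs >= NORM_RANGE[0]) & (spec.freqs <= NORM_RANGE[1])
    denom = mean_power[in_range].mean()
    if denom == 0:
        raise ValueError("zero total power in the normalization range")
    norm = mean_power / denom
    with np.errstate(divide="ignore"):
        log2p = np.log2(norm)
    return NormalizedSpectrum(freqs=spec.freqs[in_range],
                              log2_power=log2p[in_range],
                              normalized_power=norm[in_range])


def band_auc(ns: NormalizedSpectrum, band: str | tuple[float, float],
             pre_log: bool = False) -> float:
    """Trapezoidal area of the normalized spectrum over one band.

    ``band`` is a name from :data:`BANDS` or an explicit (lo, hi) in Hz
    within 0.1–50.  By default integrates the log2-normalized power (the
    plotted quantity); ``pre_log=True`` integrates the pre-log normalized
    power instead.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if lo < NORM_RANGE[0] or hi > NORM_RANGE[1] or lo > hi:
        raise ValueError(f"band ({lo}, {hi}) outside the 0.1–50 Hz grid")
    m = (ns.freqs >= lo) & (ns.freqs <= hi)
    if m.sum() < 2:
        return 0.0
    y = ns.normalized_power[m] if pre_log else ns.log2_power[m]
    return float(np.trapezoid(y, ns.freqs[m]))


def band_auc_table(ns: NormalizedSpectrum, pre_log: bool = False) -> pd.Series:
    """Band AUCs for all five canonical bands."""
    return pd.Series({b: band_auc(ns, b, pre_log=pre_log) for b in BANDS},
                     name="auc")
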