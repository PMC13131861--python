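"""Cosinor rhythm estimation and sleep-architecture statistics.

Activity traces (arbitrary units, e.g. piezo activity in 10-min bins over
5 days) are fitted with the single-component cosinor model

    y(t) = M + A·cos(2π(t − φ)/τ) + ε,

linearized as y = M + β₁cos(ωt) + β₂sin(ωt) with ω = 2π/τ, so that
A = √(β₁² + β₂²) and the acrophase φ = atan2(β₂, β₁)/ω wrapped into
[0, τ).  Time is in zeitgeber hours (ZT0 = lights-on); the default period
τ = 24 h.

Hypnograms — per-epoch Wake/NREM/REM labels — yield phase-resolved sleep
percentages (light = ZT0–12, dark = ZT12–24), bout statistics (a bout is a
maximal run of one state; bouts crossing a phase boundary are split), and
state-transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Cosinor",
    "CosinorResults",
    "Hypnogram",
    "sleep_percent",
    "bout_stats",
    "transition_counts",
]

STATES = ("Wake", "NREM", "REM")
SLEEP_STATES = ("NREM", "REM")


class Cosinor:
    """Single-component cosinor model of a periodic activity trace."""

    def __init__(self, time_h: np.ndarray, activity: np.ndarray, period_h: float = 24.0):
        t = np.asarray(time_h, dtype=float)
        y = np.asarray(activity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and activity must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(t) < 4:
            raise ValueError("need at least 4 points")
        if t[-1] - t[0] < period_h:
            raise ValueError("trace must span at least one period")
        self.t, self.y, self.period = t, y, float(period_h)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, period_h: float = 24.0,
                       time_col: str = "zt_hours", value_col: str = "activity"):
        return cls(df[time_col].to_numpy(), df[value_col].to_numpy(), period_h)

    def fit(self) -> "CosinorResults":
        """Least-squares fit; amplitude ≥ 0, acrophase in [0, period)."""
        w = 2 * np.pi / self.period
        X = np.column_stack([np.ones_like(self.t), np.cos(w * self.t), np.sin(w * self.t)])
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        mesor, b1, b2 = beta
        amplitude = float(np.hypot(b1, b2))
        scale = max(1.0, abs(float(mesor)))
        if amplitude <= 1e-12 * scale:
            amplitude = 0.0
            acrophase = np.nan  # undefined for a flat fit
        else:
            acrophase = float(np.arctan2(b2, b1) / w % self.period)
        fitted = X @ beta
        ss_res = float(((self.y - fitted) ** 2).sum())
        ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return CosinorResults(mesor=float(mesor), amplitude=amplitude,
                              acrophase_h=acrophase, period_h=self.period,
                              r_squared=r2, model=self)


@dataclass
class CosinorResults:
    """Cosinor estimates: mesor, amplitude, acrophase (h after ZT0), R²."""

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    r_squared: float
    model: Cosinor | None = None

    def predict(self, time_h: np.ndarray) -> np.ndarray:
        t = np.asarray(time_h, dtype=float)
        phi = 0.0 if np.isnan(self.acrophase_h) else self.acrophase_h
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - phi) / self.period_h
        )

    def plot(self, ax=None):
        """Observed trace with the fitted cosine overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.plot(self.model.t, self.model.y, ".", ms=2, alpha=0.5, label="observed")
            ax.plot(self.model.t, self.predict(self.model.t), lw=2, label="cosinor fit")
            ax.legend()
        ax.set_xlabel("zeitgeber time (h)")
        ax.set_ylabel("activity (a.u.)")
        return ax

    def summary(self) -> str:
        acro = "undefined" if np.isnan(self.acrophase_h) else f"ZT{self.acrophase_h:.2f}"
        return (
            "Cosinor fit\n"
            "===========\n"
            f"period:    {self.period_h:g} h\n"
            f"mesor:     {self.mesor:.4f}\n"
            f"amplitude: {self.amplitude:.4f}\n"
            f"acrophase: {acro}\n"
            f"R²:        {self.r_squared:.4f}"
        )


@dataclass
class Hypnogram:
    """Contiguous per-epoch vigilance-state labels.

    ``states`` holds one label per epoch from {Wake, NREM, REM};
    ``epoch_s`` is the epoch duration and ``start_zt`` the zeitgeber hour
    of the first epoch.
    """

    states: np.ndarray
    epoch_s: float
    start_zt: float = 0.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        unknown = set(self.states) - set(STATES)
        if unknown:
            raise ValueError(f"unknown state label(s): {sorted(unknown)}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")

    def __len__(self):
        return len(self.states)

    @property
    def duration_s(self) -> float:
        return len(self.states) * self.epoch_s

    @property
    def epoch_zt(self) -> np.ndarray:
        """ZT hour at the start of each epoch, wrapped into [0, 24)."""
        return (self.start_zt + np.arange(len(self)) * self.epoch_s / 3600.0) % 24.0

    def phase_mask(self, phase: str) -> np.ndarray:
        """Boolean mask of epochs in the light (ZT0–12) or dark phase."""
        zt = self.epoch_zt
        if phase == "light":
            return zt < 12.0
        if phase == "dark":
            return zt >= 12.0
        raise ValueError("phase must be 'light' or 'dark'")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_index": np.arange(len(self)),
            "zt_hours": self.epoch_zt,
            "state": self.states,
        })


def sleep_percent(hyp: Hypnogram, phase: str | None = None) -> float:
    """Percent of epochs scored asleep (NREM + REM), optionally per phase."""
    mask = np.ones(len(hyp), dtype=bool) if phase is None else hyp.phase_mask(phase)
    if not mask.any():
        raise ValueError(f"no epochs in phase {phase!r}")
    asleep = np.isin(hyp.states[mask], SLEEP_STATES)
    return 100.0 * float(asleep.mean())


def _runs(states: np.ndarray):
    """(state, start_index, length) for each maximal run."""
    if len(states) == 0:
        return
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, len(states)]
    for s, e in zip(starts, ends):
        yield states[s], int(s), int(e - s)


def bout_stats(hyp: Hypnogram, phase: str | None = None) -> pd.DataFrame:
    """Per-state bout counts, mean bout duration, and total time.

    A bout is a maximal run of identical epochs.  With ``phase`` given,
    bouts crossing a light/dark boundary are split there and each part
    counts toward its own phase.  ``bouts_per_day`` normalizes the count by
    the record length (phase-restricted length when a phase is given) in
    units of 24 h.
    """
    if len(hyp) == 0:
        raise ValueError("empty hypnogram")
    segments: list[tuple[str, float]] = []
    if phase is None:
        for state, _, length in _runs(hyp.states):
            segments.append((state, length * hyp.epoch_s))
        span_s = hyp.duration_s
    else:
        pm = hyp.phase_mask(phase)
        span_s = float(pm.sum()) * hyp.epoch_s
        if span_s == 0:
            raise ValueError(f"no epochs in phase {phase!r}")
        # split runs at phase boundaries: group consecutive epochs by
        # (run id, phase flag) and keep the in-phase parts
        run_id = np.r_[0, np.cumsum(hyp.states[1:] != hyp.states[:-1])]
        seg_id = np.r_[0, np.cumsum((run_id[1:] != run_id[:-1]) | (pm[1:] != pm[:-1]))]
        for sid in np.unique(seg_id):
            idx = np.flatnonzero(seg_id == sid)
            if pm[idx[0]]:
                segments.append((hyp.states[idx[0]], len(idx) * hyp.epoch_s))
    rows = []
    days = span_s / 86400.0
    for state in STATES:
        durs = [d for s, d in segments if s == state]
        rows.append({
            "state": state,
            "n_bouts": len(durs),
            "bouts_per_day": len(durs) / days if days > 0 else np.nan,
            "mean_bout_duration_s": float(np.mean(durs)) if durs else np.nan,
            "total_time_s": float(np.sum(durs)),
        })
    return pd.DataFrame(rows).set_index("state")


def transition_counts(hyp: Hypnogram) -> pd.Series:
    """Counts of state transitions keyed 'W-N', 'N-R', 'N-W', 'R-N', 'R-W'.

    Counts every label change between consecutive epochs; pairs outside the
    canonical five (e.g. a W-R jump, which the generator forbids) are still
    reported under their own key.
    """
    if len(hyp) == 0:
        raise ValueError("empty hypnogram")
    abbrev = {"Wake": "W", "NREM": "N", "REM": "R"}
    canonical = ["W-N", "N-R", "N-W", "R-N", "R-W"]
    counts: dict[str, int] = {k: 0 for k in canonical}
    prev = hyp.states[:-1]
    nxt = hyp.states[1:]
    change = prev != nxt
    for a, b in zip(prev[change], nxt[change]):
        key = f"{abbrev[a]}-{abbrev[b]}"
        counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, name="transitions")
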