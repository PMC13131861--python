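"""Seeded synthetic datasets with the structure each pipeline stage assumes.

The generators emulate the statistical shape of the study's data streams so
the full pipeline is testable without animal data:

* :func:`gen_brain_behavior` — group-structured subject × region activity
  densities and subject × behavior tables sharing a planted low-rank
  cross-block covariance (a Gaussian factor model: PLSC and Pearson
  networks are second-moment methods, so matching second moments is
  sufficient), with optional planted region-cluster correlation blocks and
  missing-completely-at-random entries in the brain table.
* :func:`gen_activity_trace` — cosine activity rhythm plus Gaussian noise,
  clipped at zero, in fixed time bins.
* :func:`gen_hypnogram` — three-state (Wake/NREM/REM) semi-Markov state
  sequence with geometric dwell times and phase-dependent entry weights;
  REM is entered only from NREM, so the only transitions produced are
  W-N, N-R, N-W, R-N and R-W.
* :func:`gen_eeg` — EEG as a sum of band-limited noise whose per-band power
  follows the state (NREM delta-dominant, REM theta-dominant, Wake
  broadband), EMG as white noise at a state-dependent RMS.
* :func:`gen_trajectory` — a bounded correlated random walk whose long-run
  zone occupancy targets a requested preference (Metropolis dynamics with
  a piecewise-constant target density), emitting centroid and nose points.

One global integer seed fans out to per-draw child streams through
``numpy.random.SeedSequence`` spawning, so identical (config, seed) pairs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sundown.ethology import Trajectory, ZoneGeometry
from sundown.rhythms import Hypnogram
from sundown.spectra import BANDS, EEGRecording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_brain_behavior",
    "gen_activity_trace",
    "gen_hypnogram",
    "gen_eeg",
    "gen_trajectory",
]


@dataclass
class SynthConfig:
    """Configuration of the brain-behavior generator.

    Defaults mirror the study design: two genotype groups of 8 subjects,
    137 mapped regions, 11 behavioral features (4 standard elevated-plus-
    maze metrics plus 7 syllable frequencies), a rank-1 planted
    brain-behavior dimension, and sparse missingness in the brain table.
    """

    seed: int = 0
    n_per_group: int = 8
    groups: tuple[str, ...] = ("Ctrl", "AD")
    n_regions: int = 137
    n_behaviors: int = 11
    latent_rank: int = 1
    latent_strength: float = 1.0
    cluster_spec: list[tuple[list[int], float]] = field(default_factory=list)
    missing_rate: float = 0.05
    noise_sd: float = 1.0
    #: indices of behavior / region columns carrying the planted dimension;
    #: None → the first 3 behaviors and first 5 regions (capped at the
    #: block size)
    behavior_loading: list[int] | None = None
    region_loading: list[int] | None = None
    #: shift of the first latent factor's mean per group index, used to
    #: plant separated group scores in the latent space
    group_effect: float = 0.0
    #: additive baselines keeping densities/times positive (arbitrary units)
    brain_baseline: float = 500.0
    behavior_baseline: float = 60.0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be at least 3")
        if self.latent_rank >= min(self.n_regions, self.n_behaviors):
            raise ValueError("latent_rank must be < min(n_regions, n_behaviors)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, r in self.cluster_spec:
            if not 0 <= r < 1:
                raise ValueError(f"infeasible within-cluster |r| target: {r}")
            if max(idx) >= self.n_regions:
                raise ValueError("cluster region index out of range")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside a generated dataset."""

    behavior_loadings: np.ndarray       # (n_behaviors, latent_rank)
    region_loadings: np.ndarray         # (n_regions, latent_rank)
    cluster_members: list[list[str]]
    null_behaviors: list[str]
    null_regions: list[str]
    latent_strength: float
    noise_sd: float


def _orthonormal_loadings(rng, n_features, subset, rank):
    """Loading matrix supported on ``subset`` with orthonormal columns."""
    W = np.zeros((n_features, rank))
    k = len(subset)
    if rank == 1:
        W[subset, 0] = 1.0 / np.sqrt(k)
    else:
        A = rng.standard_normal((k, rank))
        Q, _ = np.linalg.qr(A)
        W[subset] = Q[:, :rank]
    return W


def gen_brain_behavior(config: SynthConfig):
    """Generate aligned behavior and brain tables with planted structure.

    Returns ``(brain, behavior, truth)``: two DataFrames with
    ``subject_id``/``group`` columns, and a :class:`GroundTruth`.  Subject
    rows share ``latent_rank`` Gaussian factors loading (scaled by
    ``latent_strength``) on the designated behavior and region subsets, on
    top of independent Gaussian noise; each entry of ``cluster_spec``
    ``(region_indices, r_target)`` adds a common factor with scale
    s = σ·√(r/(1−r)), the closed-form choice making the within-cluster
    correlation s²/(s² + σ²) equal the target.  Missing entries are
    inserted MCAR in the brain table at ``missing_rate``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_load, rng_subj, rng_miss = [np.random.default_rng(s) for s in ss.spawn(3)]

    p, q, r = cfg.n_behaviors, cfg.n_regions, cfg.latent_rank
    beh_idx = cfg.behavior_loading
    if beh_idx is None:
        beh_idx = list(range(min(3, p)))
    reg_idx = cfg.region_loading
    if reg_idx is None:
        reg_idx = list(range(min(5, q)))
    Wx = _orthonormal_loadings(rng_load, p, beh_idx, r)
    Wy = _orthonormal_loadings(rng_load, q, reg_idx, r)

    beh_names = [f"beh_{i:02d}" for i in range(p)]
    reg_names = [f"reg_{i:03d}" for i in range(q)]

    frames_x, frames_y = [], []
    sid = 0
    for gi, g in enumerate(cfg.groups):
        n = cfg.n_per_group
        f = rng_subj.standard_normal((n, r))
        if cfg.group_effect:
            f[:, 0] += gi * cfg.group_effect
        X = cfg.behavior_baseline + cfg.latent_strength * f @ Wx.T \
            + cfg.noise_sd * rng_subj.standard_normal((n, p))
        Y = cfg.brain_baseline + cfg.latent_strength * f @ Wy.T \
            + cfg.noise_sd * rng_subj.standard_normal((n, q))
        for idx, r_target in cfg.cluster_spec:
            s = cfg.noise_sd * np.sqrt(r_target / (1.0 - r_target))
            shared = rng_subj.standard_normal(n)
            Y[:, idx] += s * shared[:, np.newaxis]
        X = np.maximum(X, 0.0)
        Y = np.maximum(Y, 0.0)
        ids = [f"m{sid + i:03d}" for i in range(n)]
        sid += n
        fx = pd.DataFrame(X, columns=beh_names)
        fx.insert(0, "subject_id", ids)
        fx.insert(1, "group", g)
        fy = pd.DataFrame(Y, columns=reg_names)
        fy.insert(0, "subject_id", ids)
        fy.insert(1, "group", g)
        frames_x.append(fx)
        frames_y.append(fy)
    behavior = pd.concat(frames_x, ignore_index=True)
    brain = pd.concat(frames_y, ignore_index=True)

    if cfg.missing_rate > 0:
        mask = rng_miss.random((len(brain), q)) < cfg.missing_rate
        vals = brain[reg_names].to_numpy()
        vals[mask] = np.nan
        brain[reg_names] = vals

    loaded_b = set(beh_idx) if cfg.latent_strength else set()
    loaded_r = set(reg_idx) if cfg.latent_strength else set()
    cluster_regions = {i for idx, _ in cfg.cluster_spec for i in idx}
    truth = GroundTruth(
        behavior_loadings=Wx,
        region_loadings=Wy,
        cluster_members=[[reg_names[i] for i in idx] for idx, _ in cfg.cluster_spec],
        null_behaviors=[beh_names[i] for i in range(p) if i not in loaded_b],
        null_regions=[reg_names[i] for i in range(q)
                      if i not in loaded_r and i not in cluster_regions],
        latent_strength=cfg.latent_strength,
        noise_sd=cfg.noise_sd,
    )
    return brain, behavior, truth


def gen_activity_trace(
    period_h: float = 24.0,
    amplitude: float = 0.1,
    mesor: float = 0.15,
    acrophase_h: float = 18.0,
    noise_sd: float = 0.02,
    n_days: int = 5,
    bin_min: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cosine activity rhythm in fixed bins, Gaussian noise, clipped at 0.

    Defaults emulate piezo activity: arbitrary units around 0.0–0.3 in
    10-min bins over 5 days, peaking mid dark phase (acrophase ZT18).
    Returns a DataFrame with ``zt_hours`` and ``activity`` columns.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if (24 * 60) % bin_min != 0:
        raise ValueError("bin width must divide 24 h")
    rng = np.random.default_rng(seed)
    t = np.arange(0, n_days * 24, bin_min / 60.0)
    y = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / period_h)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(len(t))
    return pd.DataFrame({"zt_hours": t, "activity": np.maximum(y, 0.0)})


DEFAULT_DWELL_S = {"Wake": 240.0, "NREM": 160.0, "REM": 60.0}
#: entry-weight multipliers: mice sleep more in the light phase
DEFAULT_PHASE_BIAS = {
    "light": {"Wake": 0.6, "NREM": 1.4, "REM": 1.4},
    "dark": {"Wake": 1.6, "NREM": 0.7, "REM": 0.7},
}
_BASE_ENTRY = {
    "Wake": {"NREM": 1.0},
    "NREM": {"REM": 0.3, "Wake": 0.7},
    "REM": {"NREM": 0.5, "Wake": 0.5},
}


def gen_hypnogram(
    dwell_params: dict[str, float] | None = None,
    phase_bias: dict[str, dict[str, float]] | None = None,
    epoch_s: float = 4.0,
    n_hours: float = 24.0,
    start_zt: float = 0.0,
    seed: int = 0,
) -> Hypnogram:
    """Three-state semi-Markov hypnogram with geometric dwell times.

    ``dwell_params`` gives mean bout lengths in seconds per state (each at
    least one epoch); a non-finite or missing REM entry excludes REM
    entirely.  Entry weights out of each state follow the physiological
    transition set — REM is reachable only from NREM — scaled by the
    light/dark multipliers in ``phase_bias``.
    """
    dwell = dict(DEFAULT_DWELL_S if dwell_params is None else dwell_params)
    bias = DEFAULT_PHASE_BIAS if phase_bias is None else phase_bias
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    excluded = {s for s in ("Wake", "NREM", "REM")
                if s not in dwell or not np.isfinite(dwell[s])}
    if "Wake" in excluded or "NREM" in excluded:
        raise ValueError("Wake and NREM states are required")
    for s, m in dwell.items():
        if s not in excluded and m < epoch_s:
            raise ValueError(f"mean dwell for {s} shorter than one epoch")

    rng = np.random.default_rng(seed)
    n_epochs = int(round(n_hours * 3600 / epoch_s))
    states = np.empty(n_epochs, dtype=object)
    pos = 0
    current = "Wake"
    while pos < n_epochs:
        mean_epochs = dwell[current] / epoch_s
        length = rng.geometric(1.0 / mean_epochs)
        end = min(pos + length, n_epochs)
        states[pos:end] = current
        pos = end
        if pos >= n_epochs:
            break
        zt = (start_zt + pos * epoch_s / 3600.0) % 24.0
        phase = "light" if zt < 12.0 else "dark"
        options = {
            s: w * bias[phase].get(s, 1.0)
            for s, w in _BASE_ENTRY[current].items()
            if s not in excluded
        }
        names = sorted(options)
        weights = np.array([options[s] for s in names], dtype=float)
        current = names[rng.choice(len(names), p=weights / weights.sum())]
    return Hypnogram(states=states, epoch_s=epoch_s, start_zt=start_zt)


DEFAULT_BAND_PROFILES = {
    "Wake": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
    "NREM": {"delta": 4.0, "theta": 1.0, "alpha": 0.5, "beta": 0.3, "gamma": 0.2},
    "REM": {"delta": 0.5, "theta": 3.0, "alpha": 0.7, "beta": 0.4, "gamma": 0.3},
}
DEFAULT_EMG_RMS = {"Wake": 30.0, "NREM": 8.0, "REM": 5.0}


def _band_limited_noise(rng, n, fs, lo, hi):
    """Unit-RMS Gaussian noise restricted to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_eeg(
    hypnogram: Hypnogram,
    fs: float = 200.0,
    band_profiles: dict[str, dict[str, float]] | None = None,
    emg_levels: dict[str, float] | None = None,
    eeg_scale: float = 20.0,
    seed: int = 0,
) -> EEGRecording:
    """EEG/EMG traces whose spectral content follows the hypnogram state.

    EEG is a sum over the five canonical bands of band-limited unit-RMS
    noise, each sample scaled by √(state band weight); EMG is white noise
    at the state's RMS.  Default profiles make NREM delta-dominant, REM
    theta-dominant and Wake broadband with high EMG — the construction the
    staging rules are meant to recover.
    """
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    profiles = DEFAULT_BAND_PROFILES if band_profiles is None else band_profiles
    emg_rms = DEFAULT_EMG_RMS if emg_levels is None else emg_levels
    ss = np.random.SeedSequence(seed)
    band_rngs = [np.random.default_rng(s) for s in ss.spawn(len(BANDS) + 1)]
    rng_emg = band_rngs[-1]

    samp_per_epoch = int(round(hypnogram.epoch_s * fs))
    n = len(hypnogram) * samp_per_epoch

    eeg = np.zeros(n)
    for (name, (lo, hi)), rng in zip(BANDS.items(), band_rngs):
        base = _band_limited_noise(rng, n, fs, lo, hi)
        w_epoch = np.array([profiles[s][name] for s in hypnogram.states])
        eeg += np.repeat(np.sqrt(w_epoch), samp_per_epoch) * base
    eeg *= eeg_scale

    rms_epoch = np.array([emg_rms[s] for s in hypnogram.states])
    emg = np.repeat(rms_epoch, samp_per_epoch) * rng_emg.standard_normal(n)
    return EEGRecording(eeg=eeg, emg=emg, fs=fs, start_zt=hypnogram.start_zt)


def gen_trajectory(
    arena: ZoneGeometry,
    zone_pref: dict[str, float],
    step_sd: float = 3.0,
    duration_s: float = 300.0,
    fps: float = 30.0,
    nose_offset_cm: float = 2.0,
    seed: int = 0,
) -> Trajectory:
    """Bounded correlated random walk targeting a zone-occupancy profile.

    The walk is Metropolis dynamics with Gaussian step proposals against a
    piecewise-constant target density proportional to
    ``zone_pref[zone] / area(zone)``, so the long-run fraction of time per
    zone approaches the normalized preference.  Proposals landing outside
    every zone (or in a zero-weight zone) are rejected.  The nose keypoint
    sits ``nose_offset_cm`` ahead of the centroid along the (smoothed)
    heading, with small jitter.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if any(w < 0 for w in zone_pref.values()):
        raise ValueError("zone weights must be non-negative")
    if step_sd < 0:
        raise ValueError("step_sd must be non-negative")
    names = list(arena.zones)
    areas = {
        n: (z.x1 - z.x0) * (z.y1 - z.y0) for n, z in arena.zones.items()
    }
    dens = {n: zone_pref.get(n, 0.0) / areas[n] for n in names}
    if all(d == 0 for d in dens.values()):
        raise ValueError("all zone weights are zero")

    def density_at(x, y):
        for n in names:                 # first matching zone wins
            if arena.zones[n].contains(np.asarray(x), np.asarray(y)):
                return dens[n]
        return 0.0

    rng = np.random.default_rng(seed)
    start_zone = max(names, key=lambda n: dens[n])
    pos = np.array(arena.zones[start_zone].center, dtype=float)
    n_frames = int(round(duration_s * fps))
    centroid = np.empty((n_frames, 2))
    heading = np.array([1.0, 0.0])
    noses = np.empty((n_frames, 2))
    proposals = rng.standard_normal((n_frames, 2)) * step_sd
    accepts = rng.random(n_frames)
    jitter = rng.standard_normal((n_frames, 2)) * 0.3
    d_here = density_at(*pos)
    for i in range(n_frames):
        cand = pos + proposals[i]
        d_cand = density_at(*cand)
        if d_here <= 0:
            ratio = 1.0 if d_cand > 0 else 0.0
        else:
            ratio = d_cand / d_here
        if d_cand > 0 and accepts[i] < min(1.0, ratio):
            step = cand - pos
            norm = np.hypot(*step)
            if norm > 1e-9:
                heading = 0.6 * heading + 0.4 * step / norm
                hn = np.hypot(*heading)
                if hn > 1e-9:
                    heading = heading / hn
            pos = cand
            d_here = d_cand
        centroid[i] = pos
        noses[i] = pos + nose_offset_cm * heading + jitter[i]
    return Trajectory(centroid=centroid, fps=fps, nose=noses)
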