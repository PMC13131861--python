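"""Arena-zone analytics for open-field and elevated-plus-maze trajectories.

Arenas are described by named rectangular zones in cm:

* **Open field (OF)** — a 50 × 50 cm box on a 5 × 5 grid of 10 × 10 cm
  cells; the centermost 3 × 3 block is the *center*, the outer ring the
  *periphery*.
* **Elevated plus maze (EPM)** — an 8 × 8 cm center with four
  26.5 × 8 cm arms (two open, two closed), plus narrow edge-bordering
  rectangles along each open-arm long edge and distal end used to detect
  head dips (nose entries over the ledge).

Trajectories carry centroid (and optionally nose) keypoints at a fixed
frame rate.  The module computes zone occupancy and entries, distance
traveled, the absent-explorer exclusion screen (immobile *and*
single-zone trials), head-dip events, and behavioral-syllable statistics
(normalized frequencies and the self-transition-free transition matrix)
downstream of pose-based syllable segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Rect",
    "ZoneGeometry",
    "open_field_geometry",
    "epm_geometry",
    "Trajectory",
    "zone_occupancy",
    "distance_traveled",
    "absent_explorer_screen",
    "head_dips",
    "syllable_frequencies",
    "syllable_transition_matrix",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] × [y0, y1] in cm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def distance(self, x, y) -> np.ndarray:
        dx = np.maximum(np.maximum(self.x0 - x, x - self.x1), 0.0)
        dy = np.maximum(np.maximum(self.y0 - y, y - self.y1), 0.0)
        return np.hypot(dx, dy)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2)


@dataclass
class ZoneGeometry:
    """Named zones of an arena plus auxiliary (non-occupancy) zones."""

    arena: str                               # "OF" or "EPM"
    zones: dict[str, Rect]
    aux_zones: dict[str, Rect] = field(default_factory=dict)

    def assign(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-point zone name; points outside all zones snap to the
        nearest zone and are flagged in the returned boolean array."""
        names = list(self.zones)
        inside = np.stack([self.zones[n].contains(x, y) for n in names])
        assigned = np.full(len(x), -1, dtype=int)
        for i, _ in enumerate(names):           # first matching zone wins
            assigned[(assigned == -1) & inside[i]] = i
        outside = assigned == -1
        if outside.any():
            d = np.stack([self.zones[n].distance(x[outside], y[outside]) for n in names])
            assigned[outside] = np.argmin(d, axis=0)
        return np.asarray(names, dtype=object)[assigned], outside


def open_field_geometry(size_cm: float = 50.0) -> ZoneGeometry:
    """50 × 50 cm open field: central 3 × 3 grid block = center."""
    cell = size_cm / 5.0
    center = Rect(cell, cell, size_cm - cell, size_cm - cell)
    # periphery is the full box; center is listed first so it wins
    periphery = Rect(0.0, 0.0, size_cm, size_cm)
    return ZoneGeometry(arena="OF", zones={"center": center, "periphery": periphery})


def epm_geometry(arm_len: float = 26.5, arm_w: float = 8.0,
                 dip_strip_w: float = 2.0) -> ZoneGeometry:
    """Elevated plus maze centered at the origin.

    Open arms run along +x/−x, closed arms along +y/−y.  Edge-bordering
    strips of width ``dip_strip_w`` just outside each open arm's long edges
    and distal end form the head-dip detection zones.
    """
    h = arm_w / 2.0
    zones = {
        "center": Rect(-h, -h, h, h),
        "open_east": Rect(h, -h, h + arm_len, h),
        "open_west": Rect(-h - arm_len, -h, -h, h),
        "closed_north": Rect(-h, h, h, h + arm_len),
        "closed_south": Rect(-h, -h - arm_len, h, -h),
    }
    s = dip_strip_w
    aux = {}
    for name, arm in (("east", zones["open_east"]), ("west", zones["open_west"])):
        aux[f"dip_{name}_top"] = Rect(arm.x0, arm.y1, arm.x1, arm.y1 + s)
        aux[f"dip_{name}_bottom"] = Rect(arm.x0, arm.y0 - s, arm.x1, arm.y0)
        if name == "east":
            aux["dip_east_end"] = Rect(arm.x1, arm.y0, arm.x1 + s, arm.y1)
        else:
            aux["dip_west_end"] = Rect(arm.x0 - s, arm.y0, arm.x0, arm.y1)
    return ZoneGeometry(arena="EPM", zones=zones, aux_zones=aux)


@dataclass
class Trajectory:
    """Keypoint track in arena-frame cm at a fixed frame rate."""

    centroid: np.ndarray                  # (n_frames, 2)
    fps: float
    nose: np.ndarray | None = None        # (n_frames, 2)

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.ndim != 2 or self.centroid.shape[1] != 2:
            raise ValueError("centroid must be (n_frames, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.nose is not None:
            self.nose = np.asarray(self.nose, dtype=float)
            if self.nose.shape != self.centroid.shape:
                raise ValueError("nose must align with centroid")

    @property
    def n_frames(self) -> int:
        return len(self.centroid)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def zone_occupancy(traj: Trajectory, zones: ZoneGeometry,
                   keypoint: str = "centroid") -> pd.DataFrame:
    """Per-zone time and entry counts from per-frame zone assignment.

    An entry is counted at every frame where the assigned zone changes into
    the zone (the first frame counts as an entry into its zone).  Frames
    outside every zone are snapped to the nearest zone; the snap count is
    stored in ``.attrs['n_outside']``.
    """
    pts = traj.nose if keypoint == "nose" else traj.centroid
    if pts is None:
        raise ValueError(f"trajectory has no {keypoint} keypoint")
    names, outside = zones.assign(pts[:, 0], pts[:, 1])
    rows = []
    for z in zones.zones:
        in_z = names == z
        entries = int(in_z[0]) + int((in_z[1:] & ~in_z[:-1]).sum())
        rows.append({"zone": z, "time_s": float(in_z.sum()) / traj.fps,
                     "entries": entries})
    out = pd.DataFrame(rows).set_index("zone")
    out.attrs["n_outside"] = int(outside.sum())
    return out


def distance_traveled(traj: Trajectory, bin_min: float | None = None):
    """Total path length (cm) of the centroid, optionally per time bin."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    steps = np.hypot(*np.diff(traj.centroid, axis=0).T)
    total = float(steps.sum())
    if bin_min is None:
        return total
    t = (np.arange(1, traj.n_frames) / traj.fps) / 60.0  # minute of each step's end
    edges = np.arange(0, np.ceil(t[-1] / bin_min) * bin_min + bin_min, bin_min)
    which = np.digitize(t, edges[1:], right=True)
    per_bin = np.bincount(which, weights=steps, minlength=len(edges) - 1)
    return total, pd.DataFrame({"bin_start_min": edges[:-1], "distance_cm": per_bin})


def absent_explorer_screen(
    traj: Trajectory,
    zones: ZoneGeometry,
    still_s: float = 180.0,
    zone_frac: float = 0.95,
    zone_s: float = 285.0,
    pos_eps_cm: float = 1.0,
) -> dict:
    """Screen for absent explorers (non-investigating trials).

    A trial is excluded only when BOTH hold: (1) some maximal run of at
    least ``still_s`` seconds during which the centroid stays within
    ``pos_eps_cm`` of the run's starting position, and (2) a single zone
    accounts for more than ``zone_frac`` of total time and more than
    ``zone_s`` seconds.  Returns the decision plus the per-criterion flags.
    """
    pts = traj.centroid
    fps = traj.fps
    # criterion 1: longest run anchored at its start position
    still = False
    longest = 0.0
    i = 0
    n = traj.n_frames
    while i < n:
        anchor = pts[i]
        d = np.hypot(pts[i:, 0] - anchor[0], pts[i:, 1] - anchor[1])
        out = np.flatnonzero(d > pos_eps_cm)
        run = out[0] if out.size else n - i
        longest = max(longest, run / fps)
        i += max(run, 1)
    still = longest >= still_s

    occ = zone_occupancy(traj, zones)
    top = occ["time_s"].max()
    dominant = (top / traj.duration_s > zone_frac) and (top > zone_s)

    return {
        "exclude": bool(still and dominant),
        "still_criterion": bool(still),
        "longest_still_s": longest,
        "zone_criterion": bool(dominant),
        "max_zone_time_s": float(top),
    }


def head_dips(traj: Trajectory, zones: ZoneGeometry) -> tuple[int, float]:
    """Count and total duration of nose entries into edge-bordering zones."""
    if traj.nose is None:
        raise ValueError("head-dip detection requires a nose keypoint")
    if not zones.aux_zones:
        raise ValueError("geometry defines no edge-bordering zones")
    x, y = traj.nose[:, 0], traj.nose[:, 1]
    in_any = np.zeros(traj.n_frames, dtype=bool)
    for rect in zones.aux_zones.values():
        in_any |= rect.contains(x, y)
    count = int(in_any[0]) + int((in_any[1:] & ~in_any[:-1]).sum())
    return count, float(in_any.sum()) / traj.fps


def syllable_frequencies(
    seq: np.ndarray,
    fps: float,
    reference_means: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Syllable onset frequencies, optionally log2-normalized to a reference.

    Raw frequency is onset events per second (an onset is the first frame of
    a run of one syllable id).  With ``reference_means`` (e.g. the mean raw
    frequency per syllable in the Ctrl Sunrise group), the normalized value
    is log2(raw / reference); syllables with a zero reference are flagged
    undefined.  Frame-occupancy fractions are also reported.
    """
    seq = np.asarray(seq)
    if len(seq) == 0:
        raise ValueError("empty syllable sequence")
    duration = len(seq) / fps
    onsets = np.r_[True, seq[1:] != seq[:-1]]
    ids = np.unique(seq)
    rows = []
    for s in ids:
        n_onsets = int((onsets & (seq == s)).sum())
        rows.append({
            "syllable": int(s),
            "frequency_hz": n_onsets / duration,
            "occupancy": float((seq == s).mean()),
        })
    out = pd.DataFrame(rows).set_index("syllable")
    if reference_means is not None:
        ref = pd.Series(reference_means)
        norm = []
        for s in out.index:
            r = ref.get(s, np.nan)
            if not np.isfinite(r) or r <= 0:
                norm.append(np.nan)
            else:
                norm.append(np.log2(out.loc[s, "frequency_hz"] / r))
        out["log2_vs_reference"] = norm
    return out


def syllable_transition_matrix(seq: np.ndarray) -> pd.DataFrame:
    """Row-stochastic syllable transition probabilities.

    Self-transitions (frame-to-frame persistence within a syllable) are
    excluded: transitions are counted only where the syllable id changes.
    Rows with no outgoing transitions are NaN and listed in
    ``.attrs['dangling']``.
    """
    seq = np.asarray(seq)
    ids = np.unique(seq)
    if len(ids) < 2:
        raise ValueError("need at least two distinct syllables")
    idx = {s: i for i, s in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)))
    change = np.flatnonzero(seq[1:] != seq[:-1])
    for c in change:
        counts[idx[seq[c]], idx[seq[c + 1]]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = counts / sums
    out = pd.DataFrame(P, index=ids, columns=ids)
    out.attrs["dangling"] = [int(ids[i]) for i in np.flatnonzero(sums[:, 0] == 0)]
    return out
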