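"""Spatial-temporal gait parameters, time-normalised kinematic curves, GVS/GPS.

Seven spatial-temporal parameters are computed from heel-marker trajectories
and gait events: cadence [steps/min], gait speed [m/s], stance, swing and
double-support percentages [%], stride length [m] and step width [m]. The
progression axis is the principal horizontal direction of heel displacement,
which keeps the parameters well-defined on curved (e.g. elliptical) walkways.

Kinematic deviation is summarised by the Gait Variable Score (GVS): the RMS
difference between a subject's 101-point time-normalised joint-angle curve
and a healthy-reference curve, for each of nine lower-limb variables; the
Gait Profile Score (GPS) aggregates the nine GVS values (RMS by default, a
plain sum optionally). Higher scores mean larger deviation from
physiological gait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KINEMATIC_VARIABLES",
    "GaitEvents",
    "MarkerTrajectories",
    "SpatioTemporal",
    "GaitProfile",
    "spatiotemporal_params",
    "time_normalize",
    "gvs",
    "gps",
    "gait_profile",
    "compare_sides",
    "reference_curves",
]

#: The nine lower-limb kinematic variables scored by GVS.
KINEMATIC_VARIABLES: tuple[str, ...] = (
    "pelvic_tilt", "pelvic_obliquity", "pelvic_rotation",
    "hip_flexion", "hip_abduction", "hip_rotation",
    "knee_flexion", "ankle_dorsiflexion", "foot_progression",
)

N_CYCLE_POINTS = 101
SIDES = ("left", "right")


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per side, strictly increasing."""

    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for d in (self.heel_strikes, self.toe_offs):
            for side in SIDES:
                d[side] = np.asarray(d.get(side, ()), float)
                if d[side].size and np.any(np.diff(d[side]) <= 0):
                    raise ValueError(f"{side} events must be strictly increasing")


@dataclass
class MarkerTrajectories:
    """Named marker trajectories: marker -> frames x (x, y, z) metres."""

    markers: dict[str, np.ndarray]
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.markers = {k: np.asarray(v, float) for k, v in self.markers.items()}
        for name, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r} must be frames x 3")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"marker {name!r} has missing frames")

    @property
    def duration(self) -> float:
        n = len(next(iter(self.markers.values())))
        return n / self.frame_rate

    def at_time(self, name: str, t: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated marker position at time(s) ``t``."""
        arr = self.markers[name]
        frames = np.arange(len(arr)) / self.frame_rate
        t = np.asarray(t, float)
        if np.any(t < frames[0] - 1e-9) or np.any(t > frames[-1] + 1e-9):
            raise ValueError("requested time outside marker trajectory span")
        return np.stack([np.interp(t, frames, arr[:, i]) for i in range(3)], axis=-1)


@dataclass(frozen=True)
class SpatioTemporal:
    cadence: float            # steps/min
    gait_speed: float         # m/s
    stance_pct: float
    swing_pct: float
    double_support_pct: float
    stride_length: float      # m
    step_width: float         # m

    def __post_init__(self) -> None:
        if abs(self.stance_pct + self.swing_pct - 100.0) > 1e-9:
            raise ValueError("stance and swing percentages must sum to 100")

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


@dataclass(frozen=True)
class GaitProfile:
    """Per-variable GVS (deg) and the aggregate GPS (deg)."""

    gvs: pd.Series
    gps: float


def _progression_axes(heel_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit progression axis (principal horizontal heel direction, oriented
    along net displacement) and the mediolateral axis perpendicular to it."""
    centred = heel_xy - heel_xy.mean(axis=0)
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    net = heel_xy[-1] - heel_xy[0]
    if axis @ net < 0:
        axis = -axis
    medio = np.array([-axis[1], axis[0]])
    return axis, medio


def spatiotemporal_params(markers: MarkerTrajectories, events: GaitEvents,
                          side: str) -> SpatioTemporal:
    """Compute the seven spatial-temporal parameters for one side."""
    if side not in SIDES:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    other = "right" if side == "left" else "left"
    hs = events.heel_strikes[side]
    if hs.size < 2:
        raise ValueError("need at least 2 ipsilateral heel strikes")
    span = markers.duration
    if hs[0] < -1e-9 or hs[-1] > span + 1e-9:
        raise ValueError("gait events outside the marker time span")

    heel = f"{side}_heel"
    heel_other = f"{other}_heel"
    stride_times = np.diff(hs)
    stride_time = float(stride_times.mean())

    track = markers.markers[heel][:, :2]
    axis, medio = _progression_axes(track)
    hs_pos = markers.at_time(heel, hs)[:, :2]
    stride_length = float(np.mean(np.diff(hs_pos @ axis)))

    # stance: first ipsilateral toe-off inside each cycle
    to = events.toe_offs[side]
    to_other = events.toe_offs[other]
    hs_other = events.heel_strikes[other]
    stance, dsup = [], []
    for k in range(len(hs) - 1):
        t0, t1 = hs[k], hs[k + 1]
        to_k = to[(to > t0) & (to < t1)]
        if to_k.size != 1:
            raise ValueError("expected exactly one ipsilateral toe-off per cycle")
        stance.append((to_k[0] - t0) / (t1 - t0) * 100.0)
        # initial DS: ipsi HS -> contra TO; terminal DS: contra HS -> ipsi TO.
        # Boundary cycles whose contralateral events fall outside the record
        # are skipped for the double-support average.
        cto = to_other[(to_other > t0) & (to_other < t1)]
        chs = hs_other[(hs_other > t0) & (hs_other < t1)]
        if cto.size == 1 and chs.size == 1:
            dsup.append(((cto[0] - t0) + (to_k[0] - chs[0])) / (t1 - t0) * 100.0)
    if not dsup:
        raise ValueError("no cycle with complete contralateral events")
    stance_pct = float(np.mean(stance))
    ds_pct = float(np.mean(dsup))

    # step width: mediolateral heel separation at contralateral heel strikes
    chs_all = hs_other[(hs_other >= hs[0]) & (hs_other <= hs[-1])]
    if chs_all.size == 0:
        raise ValueError("no contralateral heel strikes within the trial")
    sep = (markers.at_time(heel, chs_all)[:, :2]
           - markers.at_time(heel_other, chs_all)[:, :2]) @ medio
    step_width = float(np.mean(np.abs(sep)))

    return SpatioTemporal(
        cadence=120.0 / stride_time,
        gait_speed=stride_length / stride_time,
        stance_pct=stance_pct,
        swing_pct=100.0 - stance_pct,
        double_support_pct=ds_pct,
        stride_length=stride_length,
        step_width=step_width,
    )


def time_normalize(times: np.ndarray, values: np.ndarray,
                   cycle: tuple[float, float]) -> np.ndarray:
    """Resample a curve onto 101 points spanning 0-100% of a gait cycle."""
    t0, t1 = cycle
    if t1 <= t0:
        raise ValueError("degenerate cycle: end must follow start")
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("cycle outside the recorded span")
    grid = np.linspace(t0, t1, N_CYCLE_POINTS)
    return np.interp(grid, times, values)


def gvs(subject_curve: np.ndarray, reference_curve: np.ndarray) -> float:
    """Gait Variable Score: RMS difference over the 101-point gait cycle (deg)."""
    a = np.asarray(subject_curve, float)
    b = np.asarray(reference_curve, float)
    if a.shape != (N_CYCLE_POINTS,) or b.shape != (N_CYCLE_POINTS,):
        raise ValueError(f"curves must have exactly {N_CYCLE_POINTS} points")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def gps(gvs_values: np.ndarray, mode: str = "rms") -> float:
    """Gait Profile Score: aggregate of the nine GVS values.

    ``mode='rms'`` (default) is the standard root-mean-square aggregation, so
    nine equal GVS values g give GPS = g; ``mode='sum'`` gives the plain sum.
    """
    v = np.asarray(gvs_values, float)
    if v.shape != (len(KINEMATIC_VARIABLES),):
        raise ValueError(f"expected {len(KINEMATIC_VARIABLES)} GVS values")
    if np.any(v < 0):
        raise ValueError("GVS values must be non-negative")
    if mode == "rms":
        return float(np.sqrt(np.mean(v ** 2)))
    if mode == "sum":
        return float(v.sum())
    raise ValueError(f"unknown GPS mode {mode!r}")


def gait_profile(curves: pd.DataFrame, reference: pd.DataFrame,
                 mode: str = "rms") -> GaitProfile:
    """GVS per kinematic variable plus the aggregate GPS.

    ``curves`` and ``reference`` are 101-row frames with one column per
    variable in :data:`KINEMATIC_VARIABLES`.
    """
    scores = pd.Series(
        {v: gvs(curves[v].to_numpy(), reference[v].to_numpy())
         for v in KINEMATIC_VARIABLES})
    return GaitProfile(gvs=scores, gps=gps(scores.to_numpy(), mode=mode))


def compare_sides(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Paired left-right differences per parameter, one row per trial.

    Feeds the side-symmetry Wilcoxon signed-rank test; raises if the two
    sides cover different trial counts, or a single trial (no distribution).
    """
    if len(left) != len(right):
        raise ValueError("left and right must cover the same trials")
    if len(left) < 2:
        raise ValueError("need more than one trial to compare sides")
    common = [c for c in left.columns if c in right.columns]
    return (left[common].reset_index(drop=True)
            - right[common].reset_index(drop=True))


def reference_curves() -> pd.DataFrame:
    """Synthetic healthy-reference kinematic curves (deg), 101 x 9.

    Smooth parametric shapes with physiologically plausible ranges for a
    normal adult gait cycle (heel strike to heel strike). This is a
    synthetic stand-in for a normative healthy-population dataset and is the
    default reference for GVS/GPS; user-supplied references are accepted
    anywhere a reference frame is taken.
    """
    t = np.linspace(0.0, 1.0, N_CYCLE_POINTS)
    two_pi = 2 * np.pi
    curves = {
        "pelvic_tilt": 10.0 + 2.0 * np.sin(2 * two_pi * t),
        "pelvic_obliquity": 4.0 * np.sin(two_pi * t),
        "pelvic_rotation": 6.0 * np.sin(two_pi * t + 0.3),
        "hip_flexion": 20.0 * np.cos(two_pi * t) + 10.0,
        "hip_abduction": 5.0 * np.sin(two_pi * t + 0.8),
        "hip_rotation": 4.0 * np.sin(two_pi * t + 1.9),
        "knee_flexion": (18.0 * np.exp(-0.5 * ((t - 0.15) / 0.07) ** 2)
                         + 60.0 * np.exp(-0.5 * ((t - 0.72) / 0.09) ** 2)
                         + 4.0),
        "ankle_dorsiflexion": (8.0 * np.sin(two_pi * t - 0.4)
                               * np.exp(-2.0 * (t - 0.4) ** 2)),
        "foot_progression": -8.0 + 2.0 * np.sin(two_pi * t + 0.5),
    }
    return pd.DataFrame(curves)
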