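"""Synthetic dual-task studies: EEG with controlled band powers, gait trials
with condition-dependent effects, and the full 13-subject study layout.

The generator emulates the statistical structure the analysis assumes, not
the biophysics: EEG is a 1/f background plus band-limited Gaussian
components whose power can be modulated across the three difficulty levels
(1 = no task, 2 = task level 1, 3 = task level 2); transient artifacts are
Poisson-arriving high-amplitude bursts on a few channels; walking degrades
the broadband signal-to-noise ratio (10 dB by default). Gait trials advance
heel/toe markers at a configured stride length and stride time with events
consistent with the stance fraction, and joint-angle curves are a healthy
reference plus per-condition offsets plus noise.

Every non-flat level effect is recorded in the study's ground-truth registry
as a (channel, band, power_type, direction) entry, so recovery tests can
check the screening pipeline against what was actually injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from . import gait as gait_mod
from .features import BANDS
from .gait import GaitEvents, MarkerTrajectories
from .preprocess import DEFAULT_CHANNELS, EEGRecording
from .task_protocol import (ResponseLog, StimulusSchedule, TaskSpec,
                            build_schedule, schedule_duration)

__all__ = [
    "CONDITIONS",
    "SETTINGS",
    "EEGSimConfig",
    "GaitSimConfig",
    "GaitTrial",
    "SyntheticStudy",
    "simulate_eeg_recording",
    "inject_artifacts",
    "simulate_gait_trial",
    "simulate_study",
    "headline_level_effects",
]

CONDITIONS: tuple[str, ...] = ("baseline", "go_nogo_1", "go_nogo_2",
                               "n_back_1", "n_back_2")
SETTINGS: tuple[str, ...] = ("sitting", "walking")

#: Band-limited components the generator synthesises (beta emerges as
#: low_beta + high_beta, so it is not generated separately).
COMPONENT_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "low_beta",
                                    "high_beta", "gamma")

_DEFAULT_AMPLITUDES: dict[str, float] = {
    "delta": 6.0, "theta": 5.0, "alpha": 8.0,
    "low_beta": 3.0, "high_beta": 2.5, "gamma": 1.5,
}


def headline_level_effects() -> dict[tuple[str, str, str], tuple[float, float, float]]:
    """Default injected effects mirroring the study's two headline findings:
    relative delta power at Fz increases with difficulty, absolute high-beta
    power at Fz decreases. Values are multiplicative *amplitude* factors per
    level (1, 2, 3)."""
    return {
        ("Fz", "delta", "relative"): (1.0, 1.3, 1.6),
        ("Fz", "high_beta", "absolute"): (1.0, 0.85, 0.7),
    }


@dataclass(frozen=True)
class EEGSimConfig:
    """EEG generator settings.

    ``level_effects`` maps (channel, band, power_type) to a 3-vector of
    multiplicative amplitude factors applied to that channel/band component
    at levels 1-3 (power scales by the factor squared). The declared power
    type is bookkeeping for the ground-truth registry: the generator
    modulates the component's amplitude either way, which moves the absolute
    power quadratically and the relative power monotonically.
    """

    sampling_rate: float = 512.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    background_exponent: float = 1.0
    background_scale: float = 10.0           # uV RMS of the 1/f background
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    level_effects: Mapping[tuple[str, str, str], tuple[float, float, float]] = field(
        default_factory=dict)
    artifact_rate: float = 2.0               # bursts per minute
    artifact_amplitude: float = 20.0         # multiple of background RMS
    walking_noise_gain_db: float = 10.0      # broadband SNR degradation
    subject_jitter_sd: float = 0.2           # log-normal amplitude jitter

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 45.0:
            raise ValueError("sampling rate must exceed twice the 45 Hz band edge")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")
        for key, factors in self.level_effects.items():
            ch, band, ptype = key
            if ch not in self.channels:
                raise ValueError(f"level effect on unknown channel {ch!r}")
            if band not in COMPONENT_BANDS:
                raise ValueError(f"level effect on unknown component band {band!r}")
            if ptype not in ("absolute", "relative"):
                raise ValueError(f"unknown power type {ptype!r}")
            if len(factors) != 3:
                raise ValueError("level effect vectors must have length 3")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")

    def level_factor(self, channel: str, band: str, level: int) -> float:
        for (ch, b, _), factors in self.level_effects.items():
            if ch == channel and b == band:
                return float(factors[level - 1])
        return 1.0


@dataclass(frozen=True)
class GaitSimConfig:
    """Gait generator settings; condition_effects holds additive deltas on
    stride length (m) and foot-progression offset (deg) per condition."""

    stride_time: float = 1.1
    stride_length: float = 1.25
    step_width: float = 0.10
    stance_fraction: float = 0.62
    double_support_fraction: float | None = None   # derived: 2*stance - 1
    condition_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "go_nogo_1": {"stride_length": -0.08, "foot_progression": -4.0},
            "go_nogo_2": {"stride_length": -0.10, "foot_progression": -5.0},
            "n_back_1": {"stride_length": 0.0, "foot_progression": 0.0},
            "n_back_2": {"stride_length": 0.0, "foot_progression": -3.0},
        })
    curve_noise_sd: float = 1.0              # deg
    stride_noise_sd: float = 0.03            # m, cycle-to-cycle
    subject_stride_sd: float = 0.05          # m, between-subject
    n_cycles: int = 10
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        if not 0.5 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0.5, 1)")
        if self.stride_time <= 0 or self.stride_length <= 0:
            raise ValueError("stride_time and stride_length must be positive")
        ds = self.double_support_fraction
        if ds is not None and abs(ds - (2 * self.stance_fraction - 1)) > 1e-9:
            raise ValueError(
                "double_support_fraction is determined by the stance fraction "
                f"(2*stance - 1 = {2 * self.stance_fraction - 1:.3f}) for "
                "alternating bilateral gait")

    def effect(self, condition: str, key: str) -> float:
        return float(self.condition_effects.get(condition, {}).get(key, 0.0))


@dataclass
class GaitTrial:
    """One walking trial: markers, events and per-side kinematic curves."""

    markers: MarkerTrajectories
    events: GaitEvents
    curves: dict[str, pd.DataFrame]          # side -> 101 x 9 (deg)
    condition: str


@dataclass
class SyntheticStudy:
    """A full synthetic study: recordings, schedules, responses, gait trials
    and the registry of injected ground-truth effects."""

    eeg: dict[tuple[int, str, str], EEGRecording]
    schedules: dict[str, StimulusSchedule]
    task_specs: dict[str, TaskSpec]
    responses: dict[tuple[int, str, str], ResponseLog]
    gait: dict[tuple[int, str], GaitTrial]
    ground_truth: list[dict]
    n_subjects: int
    settings: tuple[str, ...]
    eeg_config: EEGSimConfig
    gait_config: GaitSimConfig
    baseline_duration: float


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit RMS."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = np.inf                          # kill DC
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_component(n: int, sfreq: float, band: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian component (4th-order Butterworth)."""
    low, high = BANDS[band]
    sos = signal.butter(4, [low, high], btype="bandpass", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_eeg_recording(config: EEGSimConfig, level: int, duration: float,
                           seed: int, setting: str = "sitting") -> EEGRecording:
    """Simulate one recording at a difficulty level (1 = no task, 2, 3).

    Each channel is an independent 1/f background plus six band-limited
    components; component power is scaled by the configured level effects.
    In the walking setting the background is boosted by
    ``walking_noise_gain_db``. Deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * config.sampling_rate))
    bg_scale = config.background_scale
    if setting == "walking":
        bg_scale *= 10.0 ** (config.walking_noise_gain_db / 20.0)
    data = np.empty((len(config.channels), n))
    for c, ch in enumerate(config.channels):
        x = bg_scale * _pink_noise(n, config.background_exponent, rng)
        for band in COMPONENT_BANDS:
            amp = config.band_amplitudes.get(band, 0.0)
            if amp <= 0:
                continue
            amp *= config.level_factor(ch, band, level)
            x = x + amp * _band_component(n, config.sampling_rate, band, rng)
        data[c] = x
    return EEGRecording(data, config.sampling_rate, config.channels)


def inject_artifacts(rec: EEGRecording, config: EEGSimConfig, seed: int,
                     ) -> tuple[EEGRecording, list[tuple[float, float]]]:
    """Add Poisson-arriving transient bursts; returns (recording, intervals).

    Bursts last 0.2-0.5 s, hit 1-3 random channels and have RMS equal to
    ``artifact_amplitude`` times that channel's pre-burst RMS. The returned
    intervals are the ground truth for cleaner evaluation.
    """
    if config.artifact_rate == 0:
        return rec.copy(), []
    rng = np.random.default_rng(seed)
    out = rec.copy()
    duration = rec.duration
    n_bursts = rng.poisson(config.artifact_rate * duration / 60.0)
    rms = rec.data.std(axis=1)
    intervals: list[tuple[float, float]] = []
    for _ in range(n_bursts):
        b_dur = rng.uniform(0.2, 0.5)
        t0 = rng.uniform(0.0, max(duration - b_dur, 0.0))
        i0 = int(t0 * rec.sfreq)
        i1 = min(int((t0 + b_dur) * rec.sfreq), rec.n_samples)
        chans = rng.choice(rec.n_channels, size=rng.integers(1, 4), replace=False)
        for c in chans:
            out.data[c, i0:i1] += (config.artifact_amplitude * rms[c]
                                   * rng.standard_normal(i1 - i0))
        intervals.append((i0 / rec.sfreq, i1 / rec.sfreq))
    intervals.sort()
    return out, intervals


def _foot_x(t: np.ndarray, stride_time: float, stride_lengths: np.ndarray,
            stance_frac: float, phase: float) -> np.ndarray:
    """Heel progression coordinate: flat during stance, linear during swing.

    ``stride_lengths`` gives the (possibly per-cycle) stride advance; cycle k
    begins at heel strike k. ``phase`` shifts the cycle origin (s)."""
    tt = t - phase
    cyc = np.floor(tt / stride_time).astype(int)
    frac = tt / stride_time - cyc
    cum = np.concatenate([[0.0], np.cumsum(stride_lengths)])
    cyc_cl = np.clip(cyc, 0, len(stride_lengths) - 1)
    swing = np.clip((frac - stance_frac) / (1.0 - stance_frac), 0.0, 1.0)
    x = cum[cyc_cl] + stride_lengths[cyc_cl] * swing
    x[cyc < 0] = 0.0
    x[cyc >= len(stride_lengths)] = cum[-1]
    return x


def simulate_gait_trial(config: GaitSimConfig, condition: str,
                        seed: int) -> GaitTrial:
    """Simulate one walking trial under a given condition.

    Heel markers rest during stance and advance by one (condition-adjusted)
    stride length during swing; right events lag the left by half a cycle.
    Angle curves are the healthy reference plus the condition's
    foot-progression offset plus Gaussian noise, identically on both sides.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    T = config.stride_time
    L = config.stride_length + config.effect(condition, "stride_length")
    n_cyc = config.n_cycles
    duration = (n_cyc + 1.5) * T
    t = np.arange(int(duration * config.frame_rate)) / config.frame_rate

    strides = {
        side: np.maximum(L + config.stride_noise_sd * rng.standard_normal(n_cyc + 2), 0.1)
        for side in ("left", "right")}
    phase = {"left": 0.0, "right": 0.5 * T}
    y_off = {"left": +config.step_width / 2.0, "right": -config.step_width / 2.0}
    markers: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        x = _foot_x(t, T, strides[side], config.stance_fraction, phase[side])
        y = np.full_like(t, y_off[side])
        z = np.zeros_like(t)
        markers[f"{side}_heel"] = np.stack([x, y, z], axis=1)
        markers[f"{side}_mth2"] = np.stack([x + 0.15, y, z], axis=1)

    s = config.stance_fraction
    hs, to = {}, {}
    for side in ("left", "right"):
        k = np.arange(n_cyc + 1)
        hs_t = phase[side] + k * T
        to_t = hs_t + s * T
        hs[side] = hs_t[hs_t <= t[-1] + 1e-9]
        to[side] = to_t[to_t <= t[-1] + 1e-9]
    events = GaitEvents(heel_strikes=hs, toe_offs=to)

    ref = gait_mod.reference_curves()
    fp_off = config.effect(condition, "foot_progression")
    curves = {}
    for side in ("left", "right"):
        frame = ref.copy()
        frame["foot_progression"] = frame["foot_progression"] + fp_off
        if config.curve_noise_sd > 0:
            frame = frame + config.curve_noise_sd * rng.standard_normal(frame.shape)
        curves[side] = frame
    return GaitTrial(markers=MarkerTrajectories(markers, config.frame_rate),
                     events=events, curves=curves, condition=condition)


def _condition_plan(go_trials: int, nback_trials: int,
                    baseline_duration: float) -> dict[str, tuple[int, TaskSpec | None, float]]:
    """condition -> (level, task spec, recording duration)."""
    plan: dict[str, tuple[int, TaskSpec | None, float]] = {
        "baseline": (1, None, baseline_duration)}
    for lvl in (1, 2):
        spec = TaskSpec.go_nogo(lvl, n_trials=go_trials)
        plan[f"go_nogo_{lvl}"] = (lvl + 1, spec, None)
        spec_nb = TaskSpec.n_back(lvl, n_trials=nback_trials)
        plan[f"n_back_{lvl}"] = (lvl + 1, spec_nb, None)
    return plan


def simulate_study(
    eeg_cfg: EEGSimConfig | None = None,
    gait_cfg: GaitSimConfig | None = None,
    n_subjects: int = 13,
    master_seed: int = 0,
    settings: tuple[str, ...] = SETTINGS,
    go_trials: int = 150,
    nback_trials: int = 75,
    baseline_duration: float = 60.0,
    response_accuracy: float = 0.95,
) -> SyntheticStudy:
    """Simulate a full study: per subject x setting x condition recordings,
    schedules and response logs, plus gait trials for every walking
    condition, all seeded deterministically from ``master_seed``.

    Subject heterogeneity is a log-normal multiplicative jitter (sd
    ``eeg_cfg.subject_jitter_sd``) on each subject's band amplitudes,
    constant across levels so it shifts a subject's overall power without
    disturbing injected level trends.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    eeg_cfg = eeg_cfg or EEGSimConfig(level_effects=headline_level_effects())
    gait_cfg = gait_cfg or GaitSimConfig()
    root = np.random.SeedSequence(master_seed)
    schedule_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_subjects + 1)]

    plan = _condition_plan(go_trials, nback_trials, baseline_duration)
    schedules, task_specs = {}, {}
    for cond, (_, spec, _) in plan.items():
        if spec is not None:
            schedules[cond] = build_schedule(spec, seed=schedule_seed)
            task_specs[cond] = spec

    eeg: dict[tuple[int, str, str], EEGRecording] = {}
    responses: dict[tuple[int, str, str], ResponseLog] = {}
    gait: dict[tuple[int, str], GaitTrial] = {}
    for subj in range(1, n_subjects + 1):
        srng = np.random.default_rng(subject_seeds[subj - 1])
        jitter = {band: float(np.exp(eeg_cfg.subject_jitter_sd
                                     * srng.standard_normal()))
                  for band in COMPONENT_BANDS}
        subj_cfg = replace(
            eeg_cfg,
            band_amplitudes={b: a * jitter.get(b, 1.0)
                             for b, a in eeg_cfg.band_amplitudes.items()})
        for setting in settings:
            for cond, (level, spec, dur) in plan.items():
                if spec is not None:
                    dur = schedule_duration(schedules[cond], spec)
                rec_seed = int(srng.integers(2 ** 31))
                rec = simulate_eeg_recording(subj_cfg, level, dur,
                                             seed=rec_seed, setting=setting)
                if eeg_cfg.artifact_rate > 0:
                    rec, _ = inject_artifacts(rec, subj_cfg,
                                              seed=int(srng.integers(2 ** 31)))
                eeg[(subj, setting, cond)] = rec
                if spec is not None:
                    responses[(subj, setting, cond)] = _simulate_responses(
                        schedules[cond], response_accuracy, srng)
        if "walking" in settings:
            subj_gait = replace(
                gait_cfg,
                stride_length=max(
                    0.3, gait_cfg.stride_length
                    + gait_cfg.subject_stride_sd * srng.standard_normal()))
            for cond in CONDITIONS:
                gait[(subj, cond)] = simulate_gait_trial(
                    subj_gait, cond, seed=int(srng.integers(2 ** 31)))

    ground_truth = []
    for (ch, band, ptype), factors in eeg_cfg.level_effects.items():
        if factors[0] == factors[1] == factors[2]:
            continue
        direction = "+" if factors[2] > factors[0] else "-"
        ground_truth.append({"channel": ch, "band": band,
                             "power_type": ptype, "direction": direction})
    return SyntheticStudy(
        eeg=eeg, schedules=schedules, task_specs=task_specs,
        responses=responses, gait=gait, ground_truth=ground_truth,
        n_subjects=n_subjects, settings=tuple(settings),
        eeg_config=eeg_cfg, gait_config=gait_cfg,
        baseline_duration=baseline_duration)


def _simulate_responses(schedule: StimulusSchedule, accuracy: float,
                        rng: np.random.Generator) -> ResponseLog:
    """A subject pressing correctly with probability ``accuracy`` per trial."""
    pairs = []
    for i in range(len(schedule)):
        if schedule.task_name == "n_back":
            want = bool(schedule.is_target[i])
        else:
            want = not bool(schedule.is_target[i])
        press = want if rng.random() < accuracy else not want
        pairs.append((i, press))
    return ResponseLog.from_pairs(pairs)
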