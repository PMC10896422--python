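"""Graded Go-NoGo and N-Back task protocols: stimulus schedules, timing, scoring.

The two auditory tasks probe distinct executive functions. Go-NoGo taxes
response inhibition: the subject presses a button on "go" stimuli and withholds
on "no-go" stimuli; difficulty is raised by shortening the inter-trial
interval (2.0 s at level 1, 1.3 s at level 2, 150 stimuli per run, hence
300 s and 195 s runs). N-Back taxes working memory: for each of 75 letter
stimuli (1.5 s per trial at both levels) the subject presses when the current
letter matches the one heard N positions earlier (N = 1 or 2).

Performance is reported as percent correct, normalised on 150 trials for
Go-NoGo and on a 44-trial scoring window for N-Back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TaskSpec",
    "StimulusSchedule",
    "ResponseLog",
    "TaskScore",
    "build_schedule",
    "schedule_duration",
    "score_responses",
]

GO_NOGO = "go_nogo"
N_BACK = "n_back"

#: Letter tokens used for the N-Back stream (8 consonants, configurable).
NBACK_TOKENS: tuple[str, ...] = ("B", "C", "D", "F", "G", "H", "J", "K")

#: Default N-Back scoring window length (percentages normalised on 44 trials).
NBACK_SCORE_WINDOW = 44

_GO_NOGO_ITI = {1: 2.0, 2: 1.3}


@dataclass(frozen=True)
class TaskSpec:
    """Configuration of one cognitive task run.

    ``inter_trial_interval`` paces Go-NoGo; ``trial_duration`` paces N-Back.
    ``load_factor`` is the N of N-Back (ignored for Go-NoGo).
    ``target_fraction`` is the no-go fraction (Go-NoGo) or the match rate over
    scorable trials (N-Back).
    """

    task_name: str
    level: int
    n_trials: int
    inter_trial_interval: float
    trial_duration: float
    load_factor: int
    target_fraction: float = 0.30
    tokens: tuple[str, ...] = NBACK_TOKENS

    def __post_init__(self) -> None:
        if self.task_name not in (GO_NOGO, N_BACK):
            raise ValueError(f"unknown task name {self.task_name!r}")
        if self.level not in (1, 2):
            raise ValueError(f"level must be 1 or 2, got {self.level}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.inter_trial_interval <= 0 or self.trial_duration <= 0:
            raise ValueError("trial pacing must be positive")
        if self.task_name == N_BACK:
            if not 0 < self.load_factor < self.n_trials:
                raise ValueError("load_factor must satisfy 0 < N < n_trials")
            if len(self.tokens) < 2:
                raise ValueError("need at least 2 N-Back tokens")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")

    @classmethod
    def go_nogo(cls, level: int, n_trials: int = 150,
                target_fraction: float = 0.30) -> "TaskSpec":
        if level not in _GO_NOGO_ITI:
            raise ValueError(f"Go-NoGo level must be 1 or 2, got {level}")
        return cls(GO_NOGO, level, n_trials, _GO_NOGO_ITI[level],
                   _GO_NOGO_ITI[level], load_factor=1,
                   target_fraction=target_fraction)

    @classmethod
    def n_back(cls, level: int, n_trials: int = 75,
               target_fraction: float = 0.30) -> "TaskSpec":
        return cls(N_BACK, level, n_trials, 1.5, 1.5, load_factor=level,
                   target_fraction=target_fraction)


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus stream: onsets (s), stimulus labels, target flags."""

    onsets: np.ndarray
    stimuli: tuple[str, ...]
    is_target: np.ndarray
    task_name: str
    level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets", np.asarray(self.onsets, float))
        object.__setattr__(self, "is_target",
                           np.asarray(self.is_target, bool))
        if len(self.onsets) != len(self.stimuli) or len(self.onsets) != len(self.is_target):
            raise ValueError("onsets/stimuli/is_target lengths differ")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass(frozen=True)
class ResponseLog:
    """Button-press log: (trial_index, pressed) pairs, at most one per trial."""

    entries: tuple[tuple[int, bool], ...]

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[int, bool]]) -> "ResponseLog":
        return cls(tuple((int(i), bool(p)) for i, p in pairs))


@dataclass(frozen=True)
class TaskScore:
    n_correct: int
    n_scored: int
    percent_correct: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_scored:
            raise ValueError("n_correct must be in [0, n_scored]")
        object.__setattr__(self, "percent_correct",
                           100.0 * self.n_correct / self.n_scored)


def build_schedule(spec: TaskSpec, seed: int) -> StimulusSchedule:
    """Build a reproducible stimulus schedule for ``spec``.

    Go-NoGo: ``n_trials`` onsets spaced by the inter-trial interval with the
    no-go fraction honoured to the nearest trial. N-Back: letter stream paced
    by ``trial_duration`` with exactly round(target_fraction * n_scorable)
    N-back matches among trials ``N .. n_trials-1``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_trials
    if spec.task_name == GO_NOGO:
        onsets = np.arange(n) * spec.inter_trial_interval
        n_nogo = int(round(spec.target_fraction * n))
        is_target = np.zeros(n, bool)
        is_target[rng.choice(n, size=n_nogo, replace=False)] = True
        stimuli = tuple("nogo" if t else "go" for t in is_target)
        return StimulusSchedule(onsets, stimuli, is_target, GO_NOGO, spec.level)

    # N-Back
    N = spec.load_factor
    onsets = np.arange(n) * spec.trial_duration
    scorable = np.arange(N, n)
    n_match = int(round(spec.target_fraction * len(scorable)))
    match_idx = set(rng.choice(scorable, size=n_match, replace=False).tolist())
    tokens = list(spec.tokens)
    seq: list[str] = []
    is_target = np.zeros(n, bool)
    for i in range(n):
        if i >= N and i in match_idx:
            seq.append(seq[i - N])
            is_target[i] = True
        else:
            choices = tokens if i < N else [t for t in tokens if t != seq[i - N]]
            seq.append(choices[rng.integers(len(choices))])
    return StimulusSchedule(onsets, tuple(seq), is_target, N_BACK, spec.level)


def schedule_duration(schedule: StimulusSchedule, spec: TaskSpec) -> float:
    """Total run duration in seconds: each trial occupies its full interval."""
    if len(schedule) == 0:
        raise ValueError("empty schedule has no duration")
    if spec.task_name == GO_NOGO:
        return spec.n_trials * spec.inter_trial_interval
    return spec.n_trials * spec.trial_duration


def _nback_score_window(spec: TaskSpec, window: int | None) -> np.ndarray:
    """Scored N-Back trial indices: trials after the first N, truncated."""
    w = NBACK_SCORE_WINDOW if window is None else int(window)
    idx = np.arange(spec.load_factor, spec.n_trials)
    return idx[:w]


def score_responses(schedule: StimulusSchedule, log: ResponseLog,
                    spec: TaskSpec, window: int | None = None) -> TaskScore:
    """Score a response log against its schedule.

    Go trials are correct iff pressed; no-go trials iff not pressed. An N-Back
    trial is correct iff the press flag matches the N-back identity of its
    token. The denominator is the full 150 trials for Go-NoGo and the 44-trial
    scoring window (configurable) for N-Back.
    """
    pressed = {}
    for idx, p in log.entries:
        if not 0 <= idx < len(schedule):
            raise ValueError(f"trial_index {idx} outside schedule")
        if idx in pressed:
            raise ValueError(f"duplicate response for trial {idx}")
        pressed[idx] = p

    if spec.task_name == GO_NOGO:
        scored = np.arange(len(schedule))
    else:
        scored = _nback_score_window(spec, window)
    n_correct = 0
    for i in scored:
        want_press = bool(schedule.is_target[i]) if spec.task_name == N_BACK \
            else not bool(schedule.is_target[i])
        if pressed.get(int(i), False) == want_press:
            n_correct += 1
    return TaskScore(n_correct=n_correct, n_scored=len(scored))
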