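"""Plain-text serialization: TSV schedules/events, wide-CSV EEG, long-CSV
markers, curves CSV, tidy feature/screen CSVs, and YAML study manifests.

A study directory written by :func:`write_study` contains one file per
artefact and a ``manifest.yaml`` listing every path plus the ground-truth
effect registry; :func:`load_study` reverses it byte-faithfully (float64
values round-trip through ``repr``)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gait import GaitEvents, MarkerTrajectories
from .preprocess import EEGRecording
from .synthetic import GaitTrial, SyntheticStudy
from .task_protocol import ResponseLog, StimulusSchedule, TaskSpec

__all__ = [
    "write_schedule", "read_schedule", "write_responses", "read_responses",
    "write_eeg_csv", "read_eeg_csv", "write_markers_csv", "read_markers_csv",
    "write_events_tsv", "read_events_tsv", "write_curves_csv",
    "read_curves_csv", "write_study", "load_study",
]

_FLOAT_FMT = "%.17g"     # lossless float64 text round-trip


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    df = pd.DataFrame({"onset_s": schedule.onsets,
                       "stimulus": schedule.stimuli,
                       "is_target": schedule.is_target.astype(int)})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_schedule(path: str | Path, task_name: str,
                  level: int) -> StimulusSchedule:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return StimulusSchedule(df["onset_s"].to_numpy(float),
                            tuple(str(s) for s in df["stimulus"]),
                            df["is_target"].to_numpy(bool), task_name, level)


def write_responses(log: ResponseLog, path: str | Path) -> None:
    df = pd.DataFrame(log.entries, columns=["trial_index", "pressed"])
    df["pressed"] = df["pressed"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_responses(path: str | Path) -> ResponseLog:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ResponseLog.from_pairs(
        list(zip(df["trial_index"].astype(int), df["pressed"].astype(bool))))


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    """Wide CSV: one column per channel (header = labels), plus sfreq stored
    in a leading comment line."""
    with open(path, "w") as fh:
        fh.write(f"# sfreq={rec.sfreq!r}\n")
        pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(
            fh, index=False, float_format=_FLOAT_FMT)


def read_eeg_csv(path: str | Path) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sfreq="):
            raise ValueError(f"{path}: missing sfreq header line")
        sfreq = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    return EEGRecording(df.to_numpy(float).T, sfreq, tuple(df.columns))


def write_markers_csv(markers: MarkerTrajectories, path: str | Path) -> None:
    """Long CSV: frame, marker, x, y, z (metres)."""
    rows = []
    for name, arr in markers.markers.items():
        df = pd.DataFrame(arr, columns=["x", "y", "z"])
        df.insert(0, "marker", name)
        df.insert(0, "frame", np.arange(len(arr)))
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={markers.frame_rate!r}\n")
        out.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_markers_csv(path: str | Path) -> MarkerTrajectories:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# frame_rate="):
            raise ValueError(f"{path}: missing frame_rate header line")
        frame_rate = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    markers = {str(name): g.sort_values("frame")[["x", "y", "z"]].to_numpy(float)
               for name, g in df.groupby("marker")}
    return MarkerTrajectories(markers, frame_rate)


def write_events_tsv(events: GaitEvents, path: str | Path) -> None:
    rows = []
    for side in ("left", "right"):
        rows += [{"side": side, "event": "heel_strike", "time_s": t}
                 for t in events.heel_strikes[side]]
        rows += [{"side": side, "event": "toe_off", "time_s": t}
                 for t in events.toe_offs[side]]
    pd.DataFrame(rows).sort_values(["side", "event", "time_s"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events_tsv(path: str | Path) -> GaitEvents:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    hs, to = {}, {}
    for side in ("left", "right"):
        sub = df[df["side"] == side]
        hs[side] = np.sort(sub.loc[sub["event"] == "heel_strike",
                                   "time_s"].to_numpy(float))
        to[side] = np.sort(sub.loc[sub["event"] == "toe_off",
                                   "time_s"].to_numpy(float))
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def write_curves_csv(curves: dict[str, pd.DataFrame], path: str | Path) -> None:
    """101-row CSV with one ``side:variable`` column per curve."""
    wide = pd.concat({side: df for side, df in curves.items()}, axis=1)
    wide.columns = [f"{side}:{var}" for side, var in wide.columns]
    wide.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curves_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        side, var = col.split(":", 1)
        out.setdefault(side, {})[var] = df[col].to_numpy(float)
    return {side: pd.DataFrame(cols) for side, cols in out.items()}


def write_study(study: SyntheticStudy, directory: str | Path) -> Path:
    """Write a study to a directory tree and return the manifest path."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "n_subjects": study.n_subjects,
        "settings": list(study.settings),
        "baseline_duration": study.baseline_duration,
        "ground_truth": study.ground_truth,
        "task_specs": {
            cond: {"task_name": s.task_name, "level": s.level,
                   "n_trials": s.n_trials,
                   "inter_trial_interval": s.inter_trial_interval,
                   "trial_duration": s.trial_duration,
                   "load_factor": s.load_factor,
                   "target_fraction": s.target_fraction}
            for cond, s in study.task_specs.items()},
        "schedules": {}, "eeg": {}, "responses": {}, "gait": {},
    }
    for cond, sched in study.schedules.items():
        rel = f"schedule_{cond}.tsv"
        write_schedule(sched, root / rel)
        manifest["schedules"][cond] = rel
    for (subj, setting, cond), rec in study.eeg.items():
        rel = f"eeg_s{subj:02d}_{setting}_{cond}.csv"
        write_eeg_csv(rec, root / rel)
        manifest["eeg"][f"{subj}|{setting}|{cond}"] = rel
    for (subj, setting, cond), log in study.responses.items():
        rel = f"responses_s{subj:02d}_{setting}_{cond}.tsv"
        write_responses(log, root / rel)
        manifest["responses"][f"{subj}|{setting}|{cond}"] = rel
    for (subj, cond), trial in study.gait.items():
        base = f"gait_s{subj:02d}_{cond}"
        write_markers_csv(trial.markers, root / f"{base}_markers.csv")
        write_events_tsv(trial.events, root / f"{base}_events.tsv")
        write_curves_csv(trial.curves, root / f"{base}_curves.csv")
        manifest["gait"][f"{subj}|{cond}"] = base
    path = root / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_study(manifest_path: str | Path) -> SyntheticStudy:
    """Load a study from a manifest; raises listing any missing files."""
    path = Path(manifest_path)
    root = path.parent
    with open(path) as fh:
        man = yaml.safe_load(fh)
    required = (list(man["schedules"].values())
                + list(man["eeg"].values()) + list(man["responses"].values())
                + [f"{b}_{suffix}" for b in man["gait"].values()
                   for suffix in ("markers.csv", "events.tsv", "curves.csv")])
    missing = [r for r in required if not (root / r).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")

    task_specs = {cond: TaskSpec(**kw) for cond, kw in man["task_specs"].items()}
    schedules = {cond: read_schedule(root / rel, task_specs[cond].task_name,
                                    task_specs[cond].level)
                 for cond, rel in man["schedules"].items()}
    eeg = {}
    for key, rel in man["eeg"].items():
        subj, setting, cond = key.split("|")
        eeg[(int(subj), setting, cond)] = read_eeg_csv(root / rel)
    responses = {}
    for key, rel in man["responses"].items():
        subj, setting, cond = key.split("|")
        responses[(int(subj), setting, cond)] = read_responses(root / rel)
    gait = {}
    for key, base in man["gait"].items():
        subj, cond = key.split("|")
        gait[(int(subj), cond)] = GaitTrial(
            markers=read_markers_csv(root / f"{base}_markers.csv"),
            events=read_events_tsv(root / f"{base}_events.tsv"),
            curves=read_curves_csv(root / f"{base}_curves.csv"),
            condition=cond)
    from .synthetic import EEGSimConfig, GaitSimConfig
    return SyntheticStudy(
        eeg=eeg, schedules=schedules, task_specs=task_specs,
        responses=responses, gait=gait, ground_truth=man["ground_truth"],
        n_subjects=int(man["n_subjects"]), settings=tuple(man["settings"]),
        eeg_config=EEGSimConfig(), gait_config=GaitSimConfig(),
        baseline_duration=float(man["baseline_duration"]))
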