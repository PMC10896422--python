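"""End-to-end study analysis: cleaning -> features -> screening -> gait stats.

``run_study_analysis`` takes a study (in memory, or a manifest YAML path
written by :mod:`dualtask_ef.io`) and reproduces the full analysis chain:

1. every recording is bandpass filtered ([0.5, 45] Hz, 4th-order Butterworth,
   zero phase) and cleaned with the variance-threshold subspace cleaner;
2. recordings are epoched by trial length (Go-NoGo 2.0 / 1.3 s, N-Back 1.5 s;
   the no-task baseline is cut into contiguous pseudo-epochs of the
   context's level-1 trial length) and the 112 band-power features averaged
   per condition;
3. each of the four analysis contexts (sitting/walking x Go-NoGo/N-Back) is
   screened for strict monotonicity over the three difficulty levels and
   Friedman-tested with Kendall's W;
4. gait trials yield the seven spatial-temporal parameters and GVS/GPS per
   side; side symmetry is Wilcoxon-tested, and the six condition comparisons
   are run with unpaired Mann-Whitney tests on left-side values;
5. task response logs are scored as percent correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import extract_condition_features, feature_table
from .gait import (KINEMATIC_VARIABLES, compare_sides, gait_profile,
                   reference_curves, spatiotemporal_params)
from .preprocess import CleanerConfig, asr_clean, bandpass_filter, epoch
from .screening import (ComparisonResult, ScreenResult,
                        gait_condition_comparisons, screen_features,
                        wilcoxon_signed_rank)
from .synthetic import CONDITIONS, SyntheticStudy
from .task_protocol import score_responses

__all__ = ["StudyAnalysis", "run_study_analysis", "CONTEXT_EPOCHS"]

TASKS = ("go_nogo", "n_back")

#: Trial/epoch duration (s) per condition within each task context; the
#: baseline uses the context's level-1 trial length.
CONTEXT_EPOCHS: dict[str, dict[str, float]] = {
    "go_nogo": {"baseline": 2.0, "go_nogo_1": 2.0, "go_nogo_2": 1.3},
    "n_back": {"baseline": 1.5, "n_back_1": 1.5, "n_back_2": 1.5},
}

SPATIOTEMPORAL_PARAMS = ("cadence", "gait_speed", "stance_pct", "swing_pct",
                         "double_support_pct", "stride_length", "step_width")


@dataclass
class StudyAnalysis:
    """All analysis outputs for one study."""

    feature_tables: dict[tuple[str, str], pd.DataFrame]
    screen_results: dict[tuple[str, str], list[ScreenResult]]
    gait_table: pd.DataFrame
    gait_comparisons: list[ComparisonResult]
    side_symmetry: pd.DataFrame
    task_scores: pd.DataFrame
    cleaning_summary: pd.DataFrame

    def screen_frame(self) -> pd.DataFrame:
        rows = []
        for (setting, task), results in self.screen_results.items():
            rows.extend(r.as_dict() for r in results)
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.gait_comparisons])

    def lookup(self, setting: str, task: str, feature: str) -> ScreenResult:
        for r in self.screen_results[(setting, task)]:
            if r.feature == feature:
                return r
        raise KeyError(feature)

    def report(self) -> str:
        """Deterministic markdown report of the main outputs."""
        lines = ["# Dual-task study analysis", ""]
        sf = self.screen_frame()
        for (setting, task) in sorted(self.screen_results):
            sub = sf[(sf["setting"] == setting) & (sf["task"] == task)]
            hits = sub[sub["passes_screen"] & (sub["friedman_p"] < 0.05)]
            lines.append(f"## Context: {setting} / {task}")
            lines.append(f"{len(hits)} of {len(sub)} features pass the "
                         "monotonicity screen with Friedman p < 0.05.")
            for _, row in hits.sort_values(["friedman_p", "feature"]).head(10).iterrows():
                lines.append(
                    f"- {row.feature}: rho={row.spearman_rho:+.0f}, "
                    f"chi2={row.friedman_chi2:.2f}, p={row.friedman_p:.4f}, "
                    f"W={row.kendalls_w:.2f} ({row.effect_size_class})")
            lines.append("")
        if len(self.gait_comparisons):
            lines.append("## Gait comparisons (Mann-Whitney, alpha = 0.05)")
            cf = self.comparisons_frame()
            for _, row in cf[cf["significant"]].sort_values(
                    ["parameter", "comparison"]).iterrows():
                lines.append(f"- {row.parameter} [{row.comparison}]: "
                             f"U={row.statistic:.1f}, p={row.p_value:.4f}")
            lines.append("")
        return "\n".join(lines)


def _baseline_onsets(duration: float, epoch_s: float) -> np.ndarray:
    n = int(np.floor(duration / epoch_s))
    if n == 0:
        raise ValueError("baseline recording shorter than one epoch")
    return np.arange(n) * epoch_s


def run_study_analysis(
    study: SyntheticStudy,
    cleaner: CleanerConfig = CleanerConfig(),
    reference: pd.DataFrame | None = None,
    alpha: float = 0.05,
    features: list[str] | None = None,
    clean: bool = True,
) -> StudyAnalysis:
    """Run the full analysis pipeline on a study. Deterministic given inputs.

    ``features`` restricts screening to a subset of feature columns (all 112
    by default); ``clean=False`` skips the subspace cleaner (bandpass only).
    """
    missing = [
        (subj, setting, cond)
        for subj in range(1, study.n_subjects + 1)
        for setting in study.settings
        for cond in CONDITIONS
        if (subj, setting, cond) not in study.eeg]
    if missing:
        raise ValueError(f"study is missing recordings for: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))

    # --- EEG: clean once per recording, feature rows per context ---
    clean_reports = []
    cleaned: dict[tuple[int, str, str], object] = {}
    for key, rec in study.eeg.items():
        filt = bandpass_filter(rec, cleaner)
        if clean:
            filt, rep = asr_clean(filt, cleaner)
            clean_reports.append({
                "subject": key[0], "setting": key[1], "condition": key[2],
                "n_windows_flagged": len(rep),
                "n_components_discarded": int(sum(n for _, n in rep))})
        cleaned[key] = filt

    feature_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for setting in study.settings:
        for task in TASKS:
            rows = []
            for subj in range(1, study.n_subjects + 1):
                for level, cond in enumerate(["baseline", f"{task}_1",
                                              f"{task}_2"], start=1):
                    rec = cleaned[(subj, setting, cond)]
                    epoch_s = CONTEXT_EPOCHS[task][cond]
                    if cond == "baseline":
                        onsets = _baseline_onsets(rec.duration, epoch_s)
                    else:
                        onsets = study.schedules[cond].onsets
                    eps = epoch(rec, onsets, epoch_s, condition=cond)
                    rows.append(extract_condition_features(
                        eps, subject=subj, setting=setting, condition=cond,
                        level=level))
            feature_tables[(setting, task)] = feature_table(rows)

    screen_results = {
        key: screen_features(tab, setting=key[0], task=key[1], alpha=alpha,
                             features=features)
        for key, tab in feature_tables.items()}

    # --- gait ---
    gait_rows, side_rows = [], []
    left_rows, right_rows = [], []
    if study.gait:
        ref = reference if reference is not None else reference_curves()
        for (subj, cond), trial in sorted(study.gait.items()):
            per_side = {}
            for side in ("left", "right"):
                st = spatiotemporal_params(trial.markers, trial.events, side)
                prof = gait_profile(trial.curves[side], ref)
                row = st.as_series()
                for var in KINEMATIC_VARIABLES:
                    row[f"gvs_{var}"] = prof.gvs[var]
                row["gps"] = prof.gps
                per_side[side] = row
            left_rows.append(pd.Series({"subject": subj, "condition": cond,
                                        **per_side["left"]}))
            right_rows.append(pd.Series({"subject": subj, "condition": cond,
                                         **per_side["right"]}))
        gait_table = pd.DataFrame(left_rows)
        right_table = pd.DataFrame(right_rows)
        params = [c for c in gait_table.columns
                  if c not in ("subject", "condition")]
        diffs = compare_sides(gait_table[params], right_table[params])
        for param in params:
            d = diffs[param].to_numpy()
            if np.all(d == 0):
                stat, p = np.nan, 1.0   # perfectly symmetric: no evidence
            else:
                stat, p = wilcoxon_signed_rank(d)
            side_rows.append({"parameter": param, "statistic": stat,
                              "p_value": p, "significant": bool(p < alpha)})
        comparisons = gait_condition_comparisons(gait_table, alpha=alpha)
    else:
        gait_table = pd.DataFrame()
        comparisons = []

    # --- task scores ---
    score_rows = []
    for (subj, setting, cond), log in sorted(study.responses.items()):
        score = score_responses(study.schedules[cond], log,
                                study.task_specs[cond])
        score_rows.append({"subject": subj, "setting": setting,
                           "condition": cond, "n_correct": score.n_correct,
                           "n_scored": score.n_scored,
                           "percent_correct": score.percent_correct})

    return StudyAnalysis(
        feature_tables=feature_tables,
        screen_results=screen_results,
        gait_table=gait_table,
        gait_comparisons=comparisons,
        side_symmetry=pd.DataFrame(side_rows),
        task_scores=pd.DataFrame(score_rows),
        cleaning_summary=pd.DataFrame(clean_reports),
    )
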