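"""Monotonicity screening and nonparametric testing across difficulty levels.

The procedure mirrors the study design: for each analysis context (sitting
or walking crossed with Go-NoGo or N-Back), every EEG feature yields a
subjects x 3 matrix over the levels (1) no task, (2) task level 1, (3) task
level 2. Features whose across-subject mean values are strictly monotone in
level (Spearman rho against the levels equal to +1 or -1) pass the screen
and are tested with a Friedman test; Kendall's W = chi2 / (n (k-1)) is the
effect size, classed as high (>= 0.8), slightly high (0.5 < W < 0.8) or
other. Per-subject Spearman coefficients reproduce the single-subject
confirmation tables.

Gait parameters are compared with Wilcoxon signed-rank tests (left vs right
side) and unpaired Wilcoxon-Mann-Whitney tests for the six condition
comparisons (walking baseline vs each task condition, and level 1 vs 2
within each task). No multiple-testing correction is applied by default,
matching the original procedure; Benjamini-Hochberg is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import feature_columns

__all__ = [
    "ScreenResult",
    "ComparisonResult",
    "spearman_level_rho",
    "screen_features",
    "friedman_test",
    "kendalls_w",
    "effect_size_class",
    "per_subject_spearman",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "GAIT_COMPARISONS",
    "gait_condition_comparisons",
]

LEVELS = np.array([1.0, 2.0, 3.0])

#: The six inter-condition gait comparisons (unpaired, across subjects).
GAIT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("baseline", "n_back_1"),
    ("baseline", "n_back_2"),
    ("baseline", "go_nogo_1"),
    ("baseline", "go_nogo_2"),
    ("n_back_1", "n_back_2"),
    ("go_nogo_1", "go_nogo_2"),
)


@dataclass(frozen=True)
class ScreenResult:
    """Screening outcome for one feature in one analysis context."""

    feature: str
    setting: str
    task: str
    spearman_rho: float
    passes_screen: bool
    friedman_chi2: float
    friedman_p: float
    kendalls_w: float
    effect_size_class: str
    per_subject_rho: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("feature", "setting", "task", "spearman_rho", "passes_screen",
              "friedman_chi2", "friedman_p", "kendalls_w",
              "effect_size_class")}
        d["n_subjects_pos"] = int(np.sum(self.per_subject_rho >= 1 - 1e-12))
        d["n_subjects_neg"] = int(np.sum(self.per_subject_rho <= -1 + 1e-12))
        return d


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    comparison: str
    statistic: float
    p_value: float
    significant: bool

    def as_dict(self) -> dict:
        return vars(self).copy()


def spearman_level_rho(values) -> float:
    """Spearman rank correlation of a length-3 series against levels (1,2,3).

    With three points the coefficient is +/-1 exactly when the series is
    strictly monotone. A constant series (zero rank variance) returns 0.0.
    """
    v = np.asarray(values, float)
    if v.shape != (3,):
        raise ValueError("expected exactly 3 level values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite level values")
    if np.all(v == v[0]):
        return 0.0
    return float(stats.spearmanr(v, LEVELS).statistic)


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a subjects x conditions matrix.

    Average-rank tie handling with the standard tie-corrected chi-square
    approximation (k-1 degrees of freedom). A matrix in which every subject
    ties all conditions carries no information and returns (0.0, 1.0).
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need a subjects x k matrix with k >= 3")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite values in the level matrix")
    if all(np.all(row == row[0]) for row in m):
        return 0.0, 1.0
    chi2, p = stats.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return float(chi2), float(p)


def kendalls_w(chi2: float, n_subjects: int, k_conditions: int) -> float:
    """Kendall's coefficient of concordance W = chi2 / (n (k - 1)), in [0, 1]."""
    if n_subjects <= 0 or k_conditions <= 1:
        raise ValueError("need n_subjects >= 1 and k_conditions >= 2")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return float(np.clip(chi2 / (n_subjects * (k_conditions - 1)), 0.0, 1.0))


def effect_size_class(w: float) -> str:
    """Cohen-style classing: high >= 0.8; slightly high in the open (0.5, 0.8)."""
    if w >= 0.8:
        return "high"
    if 0.5 < w < 0.8:
        return "slightly_high"
    return "other"


def _level_matrix(table: pd.DataFrame, feature: str, setting: str,
                  task: str) -> np.ndarray:
    """subjects x 3 matrix for one feature over (baseline, task_1, task_2)."""
    conds = ["baseline", f"{task}_1", f"{task}_2"]
    sub = table[table["setting"] == setting]
    wide = sub.pivot_table(index="subject", columns="condition",
                           values=feature, aggfunc="first")
    missing = [c for c in conds if c not in wide.columns]
    if missing or wide[conds].isna().any().any():
        raise ValueError(f"missing level data for {feature} in "
                         f"{setting}/{task}: {missing or 'NaN cells'}")
    return wide[conds].to_numpy()


def screen_features(table: pd.DataFrame, setting: str, task: str,
                    alpha: float = 0.05,
                    features: list[str] | None = None) -> list[ScreenResult]:
    """Run the monotonicity screen + Friedman test for one analysis context.

    ``table`` is a tidy feature table with columns subject, setting,
    condition and the 112 feature columns. Every feature appears in the
    output; ``passes_screen`` marks the ones whose across-subject means are
    strictly monotone in difficulty level.
    """
    feats = features if features is not None else \
        [c for c in feature_columns() if c in table.columns]
    if not feats:
        raise ValueError("no feature columns found in table")
    results = []
    for feat in feats:
        m = _level_matrix(table, feat, setting, task)
        rho = spearman_level_rho(m.mean(axis=0))
        chi2, p = friedman_test(m)
        w = kendalls_w(chi2, m.shape[0], m.shape[1])
        per_subj = np.array([spearman_level_rho(row) for row in m])
        results.append(ScreenResult(
            feature=feat, setting=setting, task=task, spearman_rho=rho,
            passes_screen=bool(abs(rho) >= 1 - 1e-12),
            friedman_chi2=chi2, friedman_p=p, kendalls_w=w,
            effect_size_class=effect_size_class(w),
            per_subject_rho=per_subj))
    return results


def per_subject_spearman(table: pd.DataFrame, feature: str, setting: str,
                         task: str) -> pd.Series:
    """Per-subject Spearman rho across the 3 levels for one feature."""
    conds = ["baseline", f"{task}_1", f"{task}_2"]
    sub = table[table["setting"] == setting]
    wide = sub.pivot_table(index="subject", columns="condition",
                           values=feature, aggfunc="first")
    out = {}
    for subj, row in wide.iterrows():
        vals = row.reindex(conds)
        if vals.isna().any():
            out[subj] = np.nan      # flagged, not silently dropped
        else:
            out[subj] = spearman_level_rho(vals.to_numpy())
    return pd.Series(out, name=feature)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default procedure is uncorrected)."""
    p = np.asarray(pvalues, float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def wilcoxon_signed_rank(a, b=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Uses the exact small-sample distribution for n <= 25 non-zero, untied
    differences and the normal approximation otherwise. All-zero differences
    are degenerate and raise.
    """
    d = np.asarray(a, float) - (np.asarray(b, float) if b is not None else 0.0)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero: degenerate test")
    exact = nz.size <= 25 and len(np.unique(np.abs(nz))) == nz.size
    res = stats.wilcoxon(nz, alternative="two-sided",
                         method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney U test on two independent samples.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def gait_condition_comparisons(gait_table: pd.DataFrame,
                               parameters: list[str] | None = None,
                               alpha: float = 0.05) -> list[ComparisonResult]:
    """The six unpaired condition comparisons for every gait parameter.

    ``gait_table`` is tidy: one row per (subject, condition) with parameter
    columns (per-subject mean values). The test is applied as an unpaired
    Wilcoxon-Mann-Whitney comparison across subjects, as in the original
    procedure; conditions are labelled baseline (walking without task),
    go_nogo_1/2 and n_back_1/2.
    """
    params = parameters if parameters is not None else [
        c for c in gait_table.columns if c not in ("subject", "condition")]
    results = []
    for param in params:
        for cond_a, cond_b in GAIT_COMPARISONS:
            va = gait_table.loc[gait_table["condition"] == cond_a, param]
            vb = gait_table.loc[gait_table["condition"] == cond_b, param]
            if va.empty or vb.empty:
                raise ValueError(f"missing condition data for {param}: "
                                 f"{cond_a} vs {cond_b}")
            u, p = mann_whitney_u(va.to_numpy(), vb.to_numpy())
            results.append(ComparisonResult(
                parameter=param,
                comparison=f"{cond_a}_vs_{cond_b}",
                statistic=u, p_value=p, significant=bool(p < alpha)))
    return results
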