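"""Rank statistics: Spearman screen, Friedman/Kendall W, Wilcoxon, Mann-Whitney.

Exhaustive-enumeration oracles are implemented here, independent of scipy,
and checked against the implementation on small inputs.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dualtask_ef.features import feature_columns
from dualtask_ef.screening import (effect_size_class, friedman_test,
                                   kendalls_w, mann_whitney_u,
                                   per_subject_spearman, screen_features,
                                   spearman_level_rho, wilcoxon_signed_rank)

# ---------------------------------------------------------------- oracles


def friedman_oracle(m):
    """Friedman chi-square from first principles (average ranks, tie correction)."""
    m = np.asarray(m, float)
    n, k = m.shape
    ranks = np.array([sps.rankdata(row) for row in m])
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    return chi2 / correction


def wilcoxon_oracle(diffs):
    """Two-sided exact p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = [np.sum(ranks[np.array(signs, bool)])
                 for signs in itertools.product([0, 1], repeat=n)]
    stats_all = np.asarray(stats_all)
    mean = ranks.sum() / 2.0
    p = np.mean(np.abs(stats_all - mean) >= np.abs(w_obs - mean) - 1e-12)
    return float(p)


def mannwhitney_oracle(a, b):
    """Two-sided exact p by enumerating all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    mean = na * len(b) / 2.0
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        r = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        us.append(r)
    us = np.asarray(us)
    p = np.mean(np.abs(us - mean) >= np.abs(u_obs - mean) - 1e-12)
    return float(p)


# ---------------------------------------------------------------- spearman


class TestSpearmanScreen:
    @pytest.mark.parametrize("values,rho", [
        ((1.0, 2.0, 3.0), 1.0),
        ((3.0, 2.0, 1.0), -1.0),
        ((1.0, 3.0, 2.0), 0.5),
    ])
    def test_three_point_coefficients(self, values, rho):
        assert spearman_level_rho(values) == pytest.approx(rho)

    def test_constant_series_not_monotone(self):
        assert spearman_level_rho((2.0, 2.0, 2.0)) == 0.0

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            spearman_level_rho((1.0, np.nan, 2.0))

    def test_pm1_iff_strictly_monotone(self, rng):
        for _ in range(100):
            v = rng.standard_normal(3)
            rho = spearman_level_rho(v)
            monotone = (v[0] < v[1] < v[2]) or (v[0] > v[1] > v[2])
            assert (abs(rho) >= 1 - 1e-12) == monotone


# ---------------------------------------------------------------- friedman


class TestFriedman:
    def test_identical_levels_no_effect(self):
        m = np.tile([[4.2, 4.2, 4.2]], (13, 1))
        chi2, p = friedman_test(m)
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_concordance_gives_n_times_k_minus_1(self, rng):
        m = np.sort(rng.standard_normal((13, 3)), axis=1)
        chi2, _ = friedman_test(m)
        assert chi2 == pytest.approx(26.0)

    def test_small_matrix_matches_hand_oracle(self, rng):
        for _ in range(25):
            m = rng.integers(0, 6, size=(4, 3)).astype(float)
            if all(np.all(r == r[0]) for r in m):
                continue
            chi2, _ = friedman_test(m)
            assert chi2 == pytest.approx(friedman_oracle(m), abs=1e-9)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.standard_normal((13, 3))
        chi2, p = friedman_test(m)
        df = pd.DataFrame({"y": m.ravel(),
                           "subject": np.repeat(np.arange(13), 3),
                           "cond": np.tile(np.arange(3), 13)})
        res = pingouin.friedman(df, dv="y", within="cond", subject="subject",
                                method="chisq")
        assert chi2 == pytest.approx(float(res["Q"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(res["p_unc"].iloc[0]), abs=1e-12)
        assert kendalls_w(chi2, 13, 3) == pytest.approx(
            float(res["W"].iloc[0]), abs=1e-9)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((2, 3)))


class TestKendallsW:
    @pytest.mark.parametrize("chi2,expected", [
        (21.40, 0.82), (24.20, 0.93), (14.00, 0.54), (0.0, 0.0)])
    def test_printed_effect_sizes(self, chi2, expected):
        assert round(kendalls_w(chi2, 13, 3), 2) == expected

    def test_direct_concordance_definition(self, rng):
        """W from chi2 equals mean squared rank deviation on tie-free data."""
        m = rng.standard_normal((9, 3))
        chi2, _ = friedman_test(m)
        ranks = np.array([sps.rankdata(r) for r in m])
        R = ranks.sum(axis=0)
        n, k = m.shape
        S = np.sum((R - n * (k + 1) / 2.0) ** 2)
        w_direct = 12.0 * S / (n ** 2 * (k ** 3 - k))
        assert kendalls_w(chi2, n, k) == pytest.approx(w_direct, abs=1e-9)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            kendalls_w(1.0, 0, 3)
        with pytest.raises(ValueError):
            kendalls_w(-1.0, 13, 3)

    def test_effect_size_class_boundaries(self):
        assert effect_size_class(0.8) == "high"
        assert effect_size_class(0.5) == "other"      # open interval
        assert effect_size_class(0.79) == "slightly_high"
        assert effect_size_class(0.501) == "slightly_high"


# ------------------------------------------------------- wilcoxon / mwu


class TestWilcoxonSignedRank:
    def test_identical_pairs_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_p_matches_enumeration_n6(self, rng):
        for _ in range(10):
            d = rng.standard_normal(6)
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(wilcoxon_oracle(d), abs=1e-12)

    def test_type_I_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            wilcoxon_signed_rank(rng.standard_normal(8))[1] < 0.05
            for _ in range(2000))
        rate = rejections / 2000
        assert abs(rate - 0.05) < 0.02    # exact test is conservative-discrete


class TestMannWhitney:
    def test_separated_samples_exact_enumeration(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert min(u, 9 - u) == 0.0
        assert p == pytest.approx(0.1)    # 2/20 arrangements as extreme

    def test_identical_samples_no_evidence(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0, 2.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=5, unique=True),
           st.lists(st.floats(-5, 5), min_size=3, max_size=5, unique=True))
    def test_exact_p_matches_enumeration(self, a, b):
        if set(a) & set(b):
            return
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mannwhitney_oracle(a, b), abs=1e-9)


# ------------------------------------------------------- feature screen


def _toy_table(rng, n_subjects=8, monotone_feature="Fz|delta|relative"):
    rows = []
    for subj in range(1, n_subjects + 1):
        base = rng.uniform(10, 20)
        for level, cond in enumerate(["baseline", "go_nogo_1", "go_nogo_2"], 1):
            row = {"subject": subj, "setting": "sitting", "condition": cond,
                   "level": level}
            for col in feature_columns():
                row[col] = rng.standard_normal()
            row[monotone_feature] = base + 2.0 * level
            rows.append(row)
    return pd.DataFrame(rows)


class TestScreenFeatures:
    def test_all_features_reported_and_injected_one_passes(self, rng):
        table = _toy_table(rng)
        results = screen_features(table, "sitting", "go_nogo")
        assert len(results) == 112
        by_feat = {r.feature: r for r in results}
        hit = by_feat["Fz|delta|relative"]
        assert hit.passes_screen and hit.spearman_rho == 1.0
        assert hit.friedman_p < 0.05
        assert hit.effect_size_class == "high"
        # the vast majority of null features must not pass jointly
        joint = sum(r.passes_screen and r.friedman_p < 0.05 for r in results)
        assert joint <= 112 * 0.2

    def test_flat_feature_screened_out(self, rng):
        table = _toy_table(rng)
        table["Cz|alpha|absolute"] = 5.0
        res = screen_features(table, "sitting", "go_nogo",
                              features=["Cz|alpha|absolute"])[0]
        assert not res.passes_screen
        assert res.spearman_rho == 0.0

    def test_missing_level_raises(self, rng):
        table = _toy_table(rng)
        with pytest.raises(ValueError):
            screen_features(table[table["condition"] != "go_nogo_2"],
                            "sitting", "go_nogo")

    def test_monotone_transform_invariance(self, rng):
        table = _toy_table(rng)
        feats = ["Fz|delta|relative", "O1|gamma|absolute"]
        before = screen_features(table, "sitting", "go_nogo", features=feats)
        transformed = table.copy()
        for f in feats:
            transformed[f] = np.exp(transformed[f] / 10.0)
        after = screen_features(transformed, "sitting", "go_nogo",
                                features=feats)
        for r_b, r_a in zip(before, after):
            # per-subject ranks are invariant; the across-subject mean screen
            # can change under nonlinear maps, but rank stats cannot
            assert r_b.friedman_chi2 == pytest.approx(r_a.friedman_chi2)
            assert r_b.kendalls_w == pytest.approx(r_a.kendalls_w)
            assert np.allclose(r_b.per_subject_rho, r_a.per_subject_rho)

    def test_per_subject_spearman_counts(self, rng):
        table = _toy_table(rng)
        rhos = per_subject_spearman(table, "Fz|delta|relative", "sitting",
                                    "go_nogo")
        assert (rhos == 1.0).all()

    def test_per_subject_null_monotone_rate(self):
        """Under exchangeability each of the 6 orderings is equally likely;
        2 of 6 are strictly monotone."""
        rng = np.random.default_rng(11)
        count = total = 0
        for _ in range(300):
            v = rng.standard_normal(3)
            count += abs(spearman_level_rho(v)) >= 1 - 1e-12
            total += 1
        p = count / total
        se = np.sqrt((1 / 3) * (2 / 3) / total)
        assert abs(p - 1 / 3) < 3 * se

    def test_tie_breaks_strict_monotonicity(self):
        assert abs(spearman_level_rho((1.0, 1.0, 2.0))) < 1.0
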