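"""Diagnostics tests: ROC/AUC, cutoff selection, correlation, ANOVA.

Each statistic is checked against an independent oracle: all-pairs
concordance for the AUC, exhaustive threshold sweeps for the cutoff,
direct counting for confusion metrics, scipy.stats for correlations and a
statsmodels GLM for the ANOVA.
"""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from amss.errors import DegenerateDataError, UndefinedValueError, ValidationError
from amss.diagnostics import (
    confusion_metrics,
    correlate,
    roc_curve,
    select_cutoff,
    two_way_anova,
    validate_score,
)
from amss.model import Cohort, Group
from amss.simulate import default_config, generate_cohort

from conftest import noise_free_config


def concordance(pos, neg):
    """Brute-force all-pairs Mann-Whitney concordance, ties 1/2."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


score_lists = st.lists(
    st.integers(0, 12).map(float), min_size=1, max_size=30
)


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve([4, 4, 5], [0, 1, 1]).auc == pytest.approx(1.0)

    def test_complete_tie(self):
        assert roc_curve([1], [1]).auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle_on_worked_example(self):
        pos = [5, 6, 4, 7, 4, 5, 6, 1]
        neg = [0, 1, 2, 1, 0, 1, 2]
        assert roc_curve(pos, neg).auc == pytest.approx(concordance(pos, neg))

    @given(pos=score_lists, neg=score_lists)
    @settings(derandomize=True, max_examples=100)
    def test_auc_equals_concordance(self, pos, neg):
        assert roc_curve(pos, neg).auc == pytest.approx(concordance(pos, neg))

    @given(pos=score_lists, neg=score_lists)
    @settings(derandomize=True, max_examples=50)
    def test_invariant_under_monotone_transform(self, pos, neg):
        transform = lambda v: math.exp(0.3 * v) - 2.0
        a = roc_curve(pos, neg)
        b = roc_curve([transform(v) for v in pos], [transform(v) for v in neg])
        assert a.auc == pytest.approx(b.auc)
        assert a.sens_chosen == pytest.approx(b.sens_chosen)
        assert a.spec_chosen == pytest.approx(b.spec_chosen)

    def test_monotone_operating_characteristics(self):
        roc = roc_curve([5, 6, 4, 7, 4, 5, 6, 1], [0, 1, 2, 1, 0, 1, 2])
        assert all(a >= b for a, b in zip(roc.sens_at, roc.sens_at[1:]))
        assert all(a <= b for a, b in zip(roc.spec_at, roc.spec_at[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([], [1.0])


class TestSelectCutoff:
    def test_separable_midpoint(self):
        roc = roc_curve([4, 5, 6], [0, 1, 2])
        assert roc.chosen_cutoff == pytest.approx(3.0)
        assert roc.sens_chosen == 1.0 and roc.spec_chosen == 1.0

    @given(pos=score_lists, neg=score_lists)
    @settings(derandomize=True, max_examples=100)
    def test_matches_exhaustive_sweep(self, pos, neg):
        roc = roc_curve(pos, neg)
        cutoff = select_cutoff(roc)
        p, n = np.asarray(pos), np.asarray(neg)

        def j_spec(c):
            sens = float(np.mean(p > c))
            spec = float(np.mean(n <= c))
            return sens + spec - 1.0, spec

        best_j, best_spec = max(j_spec(c) for c in roc.thresholds)
        got_j, got_spec = j_spec(cutoff)
        assert got_j == pytest.approx(best_j)
        assert got_spec == pytest.approx(best_spec)
        # among thresholds achieving (J, spec), the chosen one is the lowest
        winners = [
            c for c in roc.thresholds
            if j_spec(c) == pytest.approx((best_j, best_spec))
        ]
        assert cutoff == min(winners)
        assert 0.0 <= got_j <= 1.0

    def test_integer_scores_give_half_integer_cutoffs(self):
        roc = roc_curve([4, 5, 7, 8], [0, 1, 2, 3])
        assert roc.chosen_cutoff == pytest.approx(3.5)


class TestConfusionMetrics:
    def test_paper_style_counts(self):
        # 7/8 septic above the cutoff, all 7 controls below
        m = confusion_metrics([4] * 7 + [1], [0] * 7, cutoff=3.5)
        assert m.sensitivity_pct == pytest.approx(87.5)
        assert m.specificity_pct == pytest.approx(100.0)
        assert (m.tp, m.fn, m.tn, m.fp) == (7, 1, 7, 0)

    @given(pos=score_lists, neg=score_lists,
           cutoff=st.floats(-1.0, 13.0))
    @settings(derandomize=True, max_examples=100)
    def test_matches_direct_counting(self, pos, neg, cutoff):
        m = confusion_metrics(pos, neg, cutoff)
        tp = sum(1 for v in pos if v > cutoff)
        tn = sum(1 for v in neg if v <= cutoff)
        assert (m.tp, m.fn, m.tn, m.fp) == (tp, len(pos) - tp, tn, len(neg) - tn)
        assert m.sensitivity_pct == pytest.approx(100.0 * tp / len(pos))
        assert m.specificity_pct == pytest.approx(100.0 * tn / len(neg))


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0) and res.p == 0.0

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert correlate(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        res = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 6], method="pearson")
        assert res.r == pytest.approx(10.0 / math.sqrt(148.0))

    @given(
        x=st.lists(st.floats(-10, 10).map(lambda v: round(v, 2)),
                   min_size=4, max_size=20),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=60)
    def test_matches_scipy(self, x, seed):
        rng = np.random.default_rng(seed)
        y = np.asarray(x) + rng.normal(size=len(x)).round(3)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        ours = correlate(x, y, method="pearson")
        ref_r, ref_p = stats.pearsonr(x, y)
        assert ours.r == pytest.approx(float(ref_r), abs=1e-10)
        assert ours.p == pytest.approx(float(ref_p), abs=1e-8)
        ours_s = correlate(x, y, method="spearman")
        ref_s = stats.spearmanr(x, y)
        assert ours_s.r == pytest.approx(float(ref_s.statistic), abs=1e-10)

    @given(
        x=st.lists(st.floats(-5, 5).map(lambda v: round(v, 1)),
                   min_size=4, max_size=15),
        seed=st.integers(0, 1000),
    )
    @settings(derandomize=True, max_examples=40)
    def test_spearman_is_pearson_on_midranks(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(x)).round(3)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        if np.ptp(rx) == 0 or np.ptp(ry) == 0:
            return
        assert correlate(x, y, "spearman").r == pytest.approx(
            correlate(rx, ry, "pearson").r, abs=1e-12
        )

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedValueError):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1, 2], [3, 4])


def balanced_design(cell_means, n_per_cell, noise_sd, seed):
    """Balanced treatment x time layout with Gaussian noise."""
    rng = np.random.default_rng(seed)
    values, fa, fb = [], [], []
    for (a, b), mean in cell_means.items():
        draws = mean + noise_sd * rng.standard_normal(n_per_cell)
        values.extend(draws)
        fa.extend([a] * n_per_cell)
        fb.extend([b] * n_per_cell)
    return np.array(values), np.array(fa), np.array(fb)


def anova_oracle(values, fa, fb):
    """Independent GLM route (statsmodels, Type III with sum coding)."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frame = pd.DataFrame({"y": values, "a": fa, "b": fb.astype(str)})
    model = ols("y ~ C(a, Sum) * C(b, Sum)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=3)
    return {
        "treatment": (table.loc["C(a, Sum)", "F"], table.loc["C(a, Sum)", "PR(>F)"]),
        "time": (table.loc["C(b, Sum)", "F"], table.loc["C(b, Sum)", "PR(>F)"]),
        "interaction": (
            table.loc["C(a, Sum):C(b, Sum)", "F"],
            table.loc["C(a, Sum):C(b, Sum)", "PR(>F)"],
        ),
    }


class TestTwoWayAnova:
    def test_identical_cell_means_give_zero_interaction(self):
        cell_means = {("ctl", t): 1.0 + t for t in (0, 4, 12, 24)}
        cell_means.update({("sep", t): 1.0 + t for t in (0, 4, 12, 24)})
        values, fa, fb = [], [], []
        for (a, b), mean in cell_means.items():
            for offset in (-1.0, 0.0, 1.0):  # identical spread in every cell
                values.append(mean + offset)
                fa.append(a)
                fb.append(b)
        result = two_way_anova(values, fa, fb)
        assert result.effects["interaction"].F == pytest.approx(0.0, abs=1e-10)
        assert result.effects["treatment"].F == pytest.approx(0.0, abs=1e-10)

    def test_partition_identity_on_balanced_design(self):
        means = {(a, b): 2.0 * (a == "sep") + 0.5 * b for a in ("ctl", "sep")
                 for b in (0, 1)}
        y, fa, fb = balanced_design(means, n_per_cell=5, noise_sd=1.0, seed=7)
        result = two_way_anova(y, fa, fb)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        parts = sum(e.ss for e in result.effects.values()) + result.ss_within
        assert parts == pytest.approx(ss_total, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_glm_oracle_balanced_2x4(self, seed):
        means = {
            (a, b): (3.0 if a == "sep" else 0.0) + 0.2 * b + (0.1 * b if a == "sep" else 0)
            for a in ("ctl", "sep") for b in (0, 4, 12, 24)
        }
        y, fa, fb = balanced_design(means, n_per_cell=4, noise_sd=1.0, seed=seed)
        result = two_way_anova(y, fa, fb)
        oracle = anova_oracle(y, fa, fb)
        for effect, (f_ref, p_ref) in oracle.items():
            assert result.effects[effect].F == pytest.approx(f_ref, rel=1e-8)
            assert result.effects[effect].p == pytest.approx(p_ref, abs=1e-10)

    def test_unbalanced_matches_glm_oracle(self):
        rng = np.random.default_rng(11)
        fa = np.array(["ctl"] * 14 + ["sep"] * 16)
        fb = np.tile([0, 4], 15)
        y = rng.normal(size=30) + 2.0 * (fa == "sep") + 0.3 * fb
        result = two_way_anova(y, fa, fb)
        oracle = anova_oracle(y, fa, fb)
        for effect, (f_ref, p_ref) in oracle.items():
            assert result.effects[effect].F == pytest.approx(f_ref, rel=1e-8)

    def test_bonferroni_adjustment(self):
        means = {(a, b): 2.0 * (a == "sep") for a in ("ctl", "sep") for b in (0, 4, 12, 24)}
        y, fa, fb = balanced_design(means, n_per_cell=4, noise_sd=1.0, seed=3)
        result = two_way_anova(y, fa, fb)
        assert len(result.bonferroni_posttests) == 4  # one contrast per time
        for test in result.bonferroni_posttests:
            assert test.adjusted_p == pytest.approx(min(1.0, test.raw_p * 4))

    def test_zero_within_variance_degenerate(self):
        values = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0]
        fa = ["x", "x", "x", "x", "y", "y", "y", "y"]
        fb = [0, 0, 1, 1, 0, 0, 1, 1]
        with pytest.raises(DegenerateDataError):
            two_way_anova(values, fa, fb)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValidationError, match="empty design cell"):
            two_way_anova([1.0, 2.0, 3.0], ["x", "x", "y"], [0, 1, 0])


class TestValidateScore:
    def test_default_cohort_auc_high(self, default_cohort):
        report = validate_score(default_cohort)
        assert report["roc"]["auc"] > 0.9
        assert report["n_sepsis"] == 8 and report["n_control"] == 7

    def test_noise_free_cohort_perfect_metrics(self):
        cohort = generate_cohort(noise_free_config(seed=5))
        report = validate_score(cohort)
        assert report["cutoff"]["sensitivity_pct"] == pytest.approx(100.0)
        assert report["cutoff"]["specificity_pct"] == pytest.approx(100.0)
        assert report["default_cutoff"]["sensitivity_pct"] == pytest.approx(100.0)

    def test_controls_only_rejected(self, default_cohort):
        controls = Cohort(records=default_cohort.by_group(Group.CONTROL))
        with pytest.raises(ValidationError):
            validate_score(controls)

    def test_missing_timepoint_rejected(self, default_cohort):
        with pytest.raises(ValidationError, match="no observations at 6"):
            validate_score(default_cohort, score_time_h=6.0)

    def test_correlation_signs_match_expected_directions(self, default_cohort):
        report = validate_score(default_cohort)
        signs = {c["name"]: c["r"] for c in report["correlations"]}
        assert signs["amss_24h_vs_glycemia_24h"] < 0
        assert signs["amss_24h_vs_temp_24h"] < 0
        assert signs["amss_24h_vs_weight_pct_24h"] < 0
        assert signs["amss_4h_vs_nlr_24h"] > 0
        assert signs["amss_4h_vs_lymph_24h"] < 0
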