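"""Diagnostic-validation statistics.

The machinery used to validate the A-MSS as an early diagnostic:

* empirical ROC curve over midpoint thresholds, trapezoidal AUC (equal to
  the Mann-Whitney concordance with ties counted 1/2);
* cutoff selection by maximum Youden J (sensitivity + specificity - 1),
  ties broken toward higher specificity, then the lower threshold;
* confusion metrics as exact counts at a cutoff;
* Pearson / Spearman correlation with the two-sided t-transform p-value;
* fixed-effects two-way ANOVA (treatment x time) with Type-III-style sums
  of squares from a sum-coded linear model, followed by Bonferroni-adjusted
  treatment contrasts within each time level.

Conventions: a score is "positive" (septic) when strictly above the cutoff;
sensitivity is the fraction of septic animals above it, specificity the
fraction of controls at or below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, UndefinedValueError, ValidationError
from .hematology import derive_indices
from .model import Cohort, Group, relative_weight_loss
from .scoring import DEFAULT_CUTOFF, score_cohort

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "CorrelationResult",
    "EffectResult",
    "PostTest",
    "AnovaResult",
    "roc_curve",
    "select_cutoff",
    "confusion_metrics",
    "correlate",
    "two_way_anova",
    "validate_score",
]


# ---------------------------------------------------------------------------
# ROC / cutoff
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC of a score that is higher in the diseased group.

    ``thresholds`` are the candidate cutoffs: midpoints between adjacent
    distinct pooled scores, bracketed by -inf/+inf sentinels; ``sens_at`` /
    ``spec_at`` are the operating characteristics at each.  ``auc`` is the
    trapezoidal area, identical to the probability that a random positive
    outscores a random negative (ties 1/2).
    """

    thresholds: tuple[float, ...]
    sens_at: tuple[float, ...]
    spec_at: tuple[float, ...]
    auc: float
    chosen_cutoff: float
    sens_chosen: float
    spec_chosen: float


def _as_scores(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{what} must be a non-empty 1-D sequence of scores")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite scores")
    return arr


def _operating_points(pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray):
    sens = np.array([np.mean(pos > c) for c in thresholds])
    spec = np.array([np.mean(neg <= c) for c in thresholds])
    return sens, spec


def roc_curve(
    scores_positive: Sequence[float], scores_negative: Sequence[float]
) -> ROCResult:
    """ROC analysis of two score samples (positives = diseased group)."""
    pos = _as_scores(scores_positive, "scores_positive")
    neg = _as_scores(scores_negative, "scores_negative")

    pooled = np.unique(np.concatenate([pos, neg]))
    midpoints = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], midpoints, [np.inf]])
    sens, spec = _operating_points(pos, neg, thresholds)

    # threshold increasing => (1-spec, sens) runs from (1,1) down to (0,0)
    x = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], x[::-1]))

    result = ROCResult(
        thresholds=tuple(thresholds),
        sens_at=tuple(sens),
        spec_at=tuple(spec),
        auc=auc,
        chosen_cutoff=math.nan,
        sens_chosen=math.nan,
        spec_chosen=math.nan,
    )
    cutoff = select_cutoff(result)
    i = result.thresholds.index(cutoff)
    return ROCResult(
        thresholds=result.thresholds,
        sens_at=result.sens_at,
        spec_at=result.spec_at,
        auc=auc,
        chosen_cutoff=cutoff,
        sens_chosen=result.sens_at[i],
        spec_chosen=result.spec_at[i],
    )


def select_cutoff(roc: ROCResult) -> float:
    """The candidate threshold maximizing Youden's J = sens + spec - 1.

    Ties resolve toward higher specificity, then the lower threshold — on
    integer score data this yields half-integer cutoffs (e.g. 3.5).
    """
    best_index = None
    best_key = None
    for i, threshold in enumerate(roc.thresholds):
        j = roc.sens_at[i] + roc.spec_at[i] - 1.0
        key = (j, roc.spec_at[i], -threshold)
        if best_key is None or key > best_key:
            best_key = key
            best_index = i
    return roc.thresholds[best_index]


@dataclass(frozen=True)
class ConfusionMetrics:
    """Exact counts and percent sensitivity/specificity at one cutoff."""

    sensitivity_pct: float
    specificity_pct: float
    tp: int
    fn: int
    tn: int
    fp: int


def confusion_metrics(
    scores_positive: Sequence[float],
    scores_negative: Sequence[float],
    cutoff: float,
) -> ConfusionMetrics:
    """Classify both groups at ``cutoff`` (positive iff score > cutoff)."""
    pos = _as_scores(scores_positive, "scores_positive")
    neg = _as_scores(scores_negative, "scores_negative")
    tp = int(np.sum(pos > cutoff))
    fn = pos.size - tp
    tn = int(np.sum(neg <= cutoff))
    fp = neg.size - tn
    return ConfusionMetrics(
        sensitivity_pct=100.0 * tp / (tp + fn),
        specificity_pct=100.0 * tn / (tn + fp),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    method: str
    p: float


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman is Pearson applied to midranks.  The p-value uses the exact-r
    t transform ``t = r * sqrt((n-2)/(1-r^2))`` against Student's t with
    n-2 degrees of freedom; |r| = 1 gives p = 0.  Zero variance in either
    vector leaves r undefined and raises :class:`UndefinedValueError`.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    n = xa.size
    if n < 3:
        raise ValidationError(f"correlation needs n >= 3, got n = {n}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("correlation inputs must be finite")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if method == "spearman":
        xa = stats.rankdata(xa)  # midranks for ties
        ya = stats.rankdata(ya)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedValueError("zero variance in an input; r is undefined")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, method=method, p=min(p, 1.0))


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float


@dataclass(frozen=True)
class PostTest:
    label: str
    raw_p: float
    adjusted_p: float


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects treatment x time decomposition.

    ``effects`` holds "treatment", "time" and "interaction"; post-tests are
    the treatment contrasts within each time level, Bonferroni-adjusted by
    the total number of contrasts.
    """

    effects: dict[str, EffectResult]
    ss_within: float
    df_within: int
    bonferroni_posttests: list[PostTest] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "effects": {
                name: {
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "ss": e.ss,
                }
                for name, e in self.effects.items()
            },
            "ss_within": self.ss_within,
            "df_within": self.df_within,
            "bonferroni_posttests": [
                {"contrast": t.label, "raw_p": t.raw_p, "adjusted_p": t.adjusted_p}
                for t in self.bonferroni_posttests
            ],
        }


def _sum_coding(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sum-to-zero (effects) coding: one column per non-reference level."""
    cols = []
    reference = levels[-1]
    for level in levels[:-1]:
        col = np.where(labels == level, 1.0, 0.0)
        col[labels == reference] = -1.0
        cols.append(col)
    return np.column_stack(cols)


def _sse(design: np.ndarray, y: np.ndarray) -> float:
    _, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if residuals.size:
        return float(residuals[0])
    fitted = design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.sum((y - fitted) ** 2))


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA of ``values`` on treatment (``factor_a``)
    and time (``factor_b``), with interaction.

    Sums of squares come from sum-coded linear-model comparisons (drop the
    effect's columns from the full model), the Type-III-style convention
    that weights cells equally and so remains sensible for the unbalanced
    7-vs-8 design; on balanced data it reduces to the textbook partition
    SS_total = SS_A + SS_B + SS_AB + SS_within.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.shape == a.shape == b.shape) or y.ndim != 1:
        raise ValidationError("values, factor_a and factor_b must have equal 1-D shape")
    if not np.all(np.isfinite(y)):
        raise ValidationError("values must be finite")

    levels_a = np.unique(a)
    levels_b = np.unique(b)
    if levels_a.size < 2 or levels_b.size < 2:
        raise ValidationError("each factor needs at least 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((a == la) & (b == lb)):
                raise ValidationError(f"empty design cell ({la!r}, {lb!r})")

    n = y.size
    n_cells = levels_a.size * levels_b.size
    df_within = n - n_cells
    if df_within <= 0:
        raise DegenerateDataError(
            "no within-cell replication: cannot estimate the error term"
        )

    intercept = np.ones((n, 1))
    xa = _sum_coding(a, levels_a)
    xb = _sum_coding(b, levels_b)
    xab = np.column_stack(
        [xa[:, i] * xb[:, j] for i in range(xa.shape[1]) for j in range(xb.shape[1])]
    )
    full = np.hstack([intercept, xa, xb, xab])
    sse_full = _sse(full, y)
    ms_within = sse_full / df_within
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    if ms_within <= 1e-12 * scale / max(df_within, 1):
        raise DegenerateDataError(
            "zero within-cell variance: F statistics are undefined"
        )

    blocks = {"treatment": xa, "time": xb, "interaction": xab}
    effects: dict[str, EffectResult] = {}
    for name, block in blocks.items():
        reduced = np.hstack([intercept] + [blocks[k] for k in blocks if k != name])
        ss = _sse(reduced, y) - sse_full
        df_num = block.shape[1]
        f_stat = (ss / df_num) / ms_within
        effects[name] = EffectResult(
            F=max(f_stat, 0.0),
            df_num=df_num,
            df_den=df_within,
            p=float(stats.f.sf(max(f_stat, 0.0), df_num, df_within)),
            ss=max(ss, 0.0),
        )

    # Bonferroni family: treatment contrasts within each time level, using
    # the pooled error term.
    contrasts: list[tuple[str, float]] = []
    for lb in levels_b:
        for la1, la2 in combinations(levels_a, 2):
            y1 = y[(a == la1) & (b == lb)]
            y2 = y[(a == la2) & (b == lb)]
            se = math.sqrt(ms_within * (1.0 / y1.size + 1.0 / y2.size))
            t_stat = (y1.mean() - y2.mean()) / se
            raw_p = 2.0 * float(stats.t.sf(abs(t_stat), df=df_within))
            contrasts.append((f"{la1} vs {la2} @ {lb}", raw_p))
    k = len(contrasts)
    posttests = [
        PostTest(label=label, raw_p=raw_p, adjusted_p=min(1.0, raw_p * k))
        for label, raw_p in contrasts
    ]
    return AnovaResult(
        effects=effects,
        ss_within=sse_full,
        df_within=df_within,
        bonferroni_posttests=posttests,
    )


# ---------------------------------------------------------------------------
# End-to-end validation report
# ---------------------------------------------------------------------------

def _amss_by_mouse(scored: pd.DataFrame, time_h: float, column: str) -> dict[str, float]:
    at_time = scored[np.isclose(scored["time_h"].astype(float), time_h)]
    out: dict[str, float] = {}
    for _, row in at_time.iterrows():
        if pd.notna(row[column]):
            out[row["mouse_id"]] = float(row[column])
    return out


def _paired(xs: dict[str, float], ys: dict[str, float]):
    mice = sorted(set(xs) & set(ys))
    return [xs[m] for m in mice], [ys[m] for m in mice]


def _try_correlation(name: str, xs: dict, ys: dict, method: str = "pearson") -> dict:
    x, y = _paired(xs, ys)
    try:
        res = correlate(x, y, method=method)
        return {"name": name, "method": method, "r": res.r, "n": res.n, "p": res.p}
    except (ValidationError, UndefinedValueError) as exc:
        return {"name": name, "method": method, "r": None, "n": len(x),
                "p": None, "skipped": str(exc)}


def validate_score(
    cohort: Cohort,
    score_time_h: float = 4.0,
    outcome_time_h: float = 24.0,
) -> dict:
    """Reproduce the full diagnostic-validation analysis on any cohort.

    Computes (i) the ROC of the A-MSS at ``score_time_h`` against group
    membership, with the Youden-selected cutoff and confusion metrics there
    and at the default cutoff 3.5; (ii) correlations of the early A-MSS
    against late (``outcome_time_h``) hematological severity markers
    (lymphocytes, WBC, platelets, NLR) and of the late scores against
    glycemia, temperature and weight (percent of baseline); (iii) a
    treatment x time ANOVA of the A-MSS total.  Returns a JSON-serializable
    report.
    """
    times = cohort.timepoints()
    for needed in (score_time_h, outcome_time_h):
        if not any(math.isclose(t, needed, abs_tol=1e-9) for t in times):
            raise ValidationError(
                f"cohort has no observations at {needed} h (times: {times})"
            )

    scored = score_cohort(cohort)
    amss_early = _amss_by_mouse(scored, score_time_h, "amss_total")
    group_of = {r.mouse_id: r.group for r in cohort.records}
    pos = [v for m, v in amss_early.items() if group_of[m] == Group.SEPSIS]
    neg = [v for m, v in amss_early.items() if group_of[m] == Group.CONTROL]
    if not pos or not neg:
        raise ValidationError(
            "both control and sepsis animals with complete A-MSS at the score "
            "timepoint are required for ROC validation"
        )

    roc = roc_curve(pos, neg)
    chosen = confusion_metrics(pos, neg, roc.chosen_cutoff)
    default = confusion_metrics(pos, neg, DEFAULT_CUTOFF)

    # late hematological severity markers, per mouse
    late_hema: dict[str, dict[str, float]] = {"lymph": {}, "wbc": {}, "plt": {}, "nlr": {}}
    late_phys: dict[str, dict[str, float]] = {"glycemia": {}, "temp": {}, "weight_pct": {}}
    for record in cohort.records:
        obs = record.at(outcome_time_h)
        if obs is None:
            continue
        if obs.hematology is not None:
            panel = obs.hematology
            idx = derive_indices(panel, baseline_plt=record.baseline_plt)
            for key, value in (
                ("lymph", panel.lymph), ("wbc", panel.wbc),
                ("plt", panel.plt), ("nlr", idx.nlr),
            ):
                if value is not None:
                    late_hema[key][record.mouse_id] = float(value)
        if obs.glycemia_mgdl is not None:
            late_phys["glycemia"][record.mouse_id] = obs.glycemia_mgdl
        if obs.temp_c is not None:
            late_phys["temp"][record.mouse_id] = obs.temp_c
        try:
            loss = relative_weight_loss(record, outcome_time_h)
            late_phys["weight_pct"][record.mouse_id] = 100.0 - loss
        except UndefinedValueError:
            pass

    mss_late = _amss_by_mouse(scored, outcome_time_h, "mss_subtotal")
    amss_late = _amss_by_mouse(scored, outcome_time_h, "amss_total")
    correlations = [
        _try_correlation(f"amss_{_fmt_h(score_time_h)}_vs_{key}_{_fmt_h(outcome_time_h)}",
                         amss_early, series)
        for key, series in late_hema.items()
    ]
    for score_name, series_map in (("mss", mss_late), ("amss", amss_late)):
        for key, series in late_phys.items():
            correlations.append(
                _try_correlation(
                    f"{score_name}_{_fmt_h(outcome_time_h)}_vs_{key}_{_fmt_h(outcome_time_h)}",
                    series_map, series,
                )
            )

    complete = scored[scored["complete"]]
    try:
        anova = two_way_anova(
            complete["amss_total"].astype(float).to_numpy(),
            complete["group"].to_numpy(),
            complete["time_h"].astype(float).to_numpy(),
        ).to_dict()
    except (ValidationError, DegenerateDataError) as exc:
        anova = {"error": str(exc)}

    return {
        "score_time_h": float(score_time_h),
        "outcome_time_h": float(outcome_time_h),
        "n_sepsis": len(pos),
        "n_control": len(neg),
        "roc": {
            "auc": roc.auc,
            # sentinels rendered as strings to keep the report strict JSON
            "thresholds": [
                float(t) if math.isfinite(t) else ("inf" if t > 0 else "-inf")
                for t in roc.thresholds
            ],
            "sens_at": [float(s) for s in roc.sens_at],
            "spec_at": [float(s) for s in roc.spec_at],
        },
        "cutoff": {
            "chosen": float(roc.chosen_cutoff),
            "youden_j": roc.sens_chosen + roc.spec_chosen - 1.0,
            "sensitivity_pct": chosen.sensitivity_pct,
            "specificity_pct": chosen.specificity_pct,
            "tp": chosen.tp, "fn": chosen.fn, "tn": chosen.tn, "fp": chosen.fp,
        },
        "default_cutoff": {
            "cutoff": DEFAULT_CUTOFF,
            "sensitivity_pct": default.sensitivity_pct,
            "specificity_pct": default.specificity_pct,
        },
        "correlations": correlations,
        "anova_amss": anova,
    }


def _fmt_h(time_h: float) -> str:
    return f"{time_h:g}h"
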