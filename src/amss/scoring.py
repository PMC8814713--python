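"""The Adapted Murine Sepsis Score (A-MSS).

The classic Murine Sepsis Score (MSS) grades seven observational welfare
items — appearance, level of consciousness, activity, response to stimulus,
eyes, respiration rate, respiration quality — each on an ordinal 0-4 scale
(total 0-28).  The A-MSS adds three binned quantitative items: rectal
temperature, glycemia, and relative body-weight loss, extending the total to
0-40.  Higher is sicker throughout, with one deliberate exception: mild
hyperthermia (> 38 °C, an early febrile response) scores 1 while deep
hypothermia (< 34 °C) scores 4.

Band conventions at shared printed endpoints (documented, deterministic):

* temperature: 36 and 38 both belong to the healthy band 0 (bands 1 and 2
  are open on those sides);
* glycemia: the overlap at 148 mg/dL resolves to the healthier band 0, and
  the band-3/band-4 boundary at 40 is closed in band 4 (``<=40``);
* weight loss: bands are left-open/right-closed, so exactly 5 % scores 0 and
  exactly 20 % scores 3, consistent with the strict "> 20" of band 4;
  weight gain (negative loss) scores 0.

Incomplete observations are never silently totalled: a missing item leaves
the MSS subtotal and/or A-MSS total undefined and the breakdown flagged
incomplete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .errors import ValidationError
from .model import Cohort, ITEM_FIELDS, Observation

__all__ = [
    "QUANTITATIVE_FIELDS",
    "ALL_ITEM_FIELDS",
    "AMSS_MAX",
    "MSS_MAX",
    "DEFAULT_CUTOFF",
    "Classification",
    "ScoreBreakdown",
    "score_temperature",
    "score_glycemia",
    "score_weight_loss",
    "score_observation",
    "score_cohort",
    "classify",
    "RUBRIC",
    "rubric_markdown",
]

QUANTITATIVE_FIELDS = ("temperature", "glycemia", "weight_loss")
ALL_ITEM_FIELDS = ITEM_FIELDS + QUANTITATIVE_FIELDS
MSS_MAX = 4 * len(ITEM_FIELDS)        # 28
AMSS_MAX = 4 * len(ALL_ITEM_FIELDS)   # 40

#: Diagnostic cutoff on the A-MSS total: totals strictly above it are called
#: septic.  With integer totals, 3.5 separates {<=3} from {>=4}.
DEFAULT_CUTOFF = 3.5


class Classification(str, Enum):
    SEPTIC = "septic"
    NON_SEPTIC = "non_septic"


def _require_finite(value: float, what: str) -> None:
    if value is None or not math.isfinite(value):
        raise ValidationError(f"{what} must be a finite number, got {value!r}")


def score_temperature(temp_c: float) -> int:
    """Ordinal severity of rectal temperature (°C).

    36-38 → 0; > 38 → 1; [35, 36) → 2; [34, 35) → 3; < 34 → 4.
    Note the non-monotonicity: hyperthermia scores 1, hypothermia up to 4.
    """
    _require_finite(temp_c, "temp_c")
    if temp_c > 38.0:
        return 1
    if temp_c >= 36.0:
        return 0
    if temp_c >= 35.0:
        return 2
    if temp_c >= 34.0:
        return 3
    return 4


def score_glycemia(glycemia_mgdl: float) -> int:
    """Ordinal severity of blood glucose (mg/dL).

    >= 148 → 0; [122, 148) → 1; [58, 122) → 2; (40, 58) → 3; <= 40 → 4.
    Monotone non-increasing in glycemia (hypoglycemia is the severe end).
    """
    _require_finite(glycemia_mgdl, "glycemia_mgdl")
    if glycemia_mgdl <= 0:
        raise ValidationError(f"glycemia_mgdl must be positive, got {glycemia_mgdl}")
    if glycemia_mgdl >= 148.0:
        return 0
    if glycemia_mgdl >= 122.0:
        return 1
    if glycemia_mgdl >= 58.0:
        return 2
    if glycemia_mgdl > 40.0:
        return 3
    return 4


def score_weight_loss(loss_pct: float) -> int:
    """Ordinal severity of relative body-weight loss (%).

    <= 5 → 0; (5, 10] → 1; (10, 15] → 2; (15, 20] → 3; > 20 → 4.
    Negative loss (weight gain) scores 0.
    """
    _require_finite(loss_pct, "loss_pct")
    if loss_pct <= 5.0:
        return 0
    if loss_pct <= 10.0:
        return 1
    if loss_pct <= 15.0:
        return 2
    if loss_pct <= 20.0:
        return 3
    return 4


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-item A-MSS scores for one observation.

    ``per_item`` maps each of the ten item names to its 0-4 score, or to
    ``None`` when the underlying measurement is missing.  ``mss_subtotal``
    (0-28) is defined when all seven observational items are present;
    ``amss_total`` (0-40) when all ten items are — otherwise they are
    ``None`` and ``complete`` is False.  Partial sums are never reported.
    """

    per_item: dict[str, Optional[int]]
    mss_subtotal: Optional[int]
    amss_total: Optional[int]
    complete: bool


def score_observation(
    obs: Observation, baseline_weight_g: Optional[float] = None
) -> ScoreBreakdown:
    """Score one observation against the full ten-item rubric.

    The three quantitative items are computed from raw physiology
    (weight-loss needs the animal's baseline weight); the seven
    observational items are validated pass-throughs.  Missing inputs leave
    the corresponding item (and hence the totals) undefined.
    """
    per_item: dict[str, Optional[int]] = dict(obs.items())
    per_item["temperature"] = (
        score_temperature(obs.temp_c) if obs.temp_c is not None else None
    )
    per_item["glycemia"] = (
        score_glycemia(obs.glycemia_mgdl) if obs.glycemia_mgdl is not None else None
    )
    if baseline_weight_g is not None and obs.weight_g is not None:
        loss = 100.0 * (baseline_weight_g - obs.weight_g) / baseline_weight_g
        per_item["weight_loss"] = score_weight_loss(loss)
    else:
        per_item["weight_loss"] = None

    observational = [per_item[name] for name in ITEM_FIELDS]
    mss_subtotal = sum(observational) if None not in observational else None
    quantitative = [per_item[name] for name in QUANTITATIVE_FIELDS]
    complete = mss_subtotal is not None and None not in quantitative
    amss_total = mss_subtotal + sum(quantitative) if complete else None
    return ScoreBreakdown(
        per_item=per_item,
        mss_subtotal=mss_subtotal,
        amss_total=amss_total,
        complete=complete,
    )


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Score every observation in a cohort.

    One row per observation with mouse_id, group, time_h, the ten per-item
    scores (``score_<item>``, nullable integers), mss_subtotal, amss_total
    and the complete flag.  The weight-loss baseline is each animal's
    earliest recorded weight.
    """
    rows = []
    for record in cohort.records:
        baseline_w = record.baseline_weight_g
        for obs in record.observations:
            breakdown = score_observation(obs, baseline_weight_g=baseline_w)
            row: dict = {
                "mouse_id": record.mouse_id,
                "group": record.group.value,
                "time_h": obs.time_h,
            }
            row.update(
                {f"score_{name}": breakdown.per_item[name] for name in ALL_ITEM_FIELDS}
            )
            row["mss_subtotal"] = breakdown.mss_subtotal
            row["amss_total"] = breakdown.amss_total
            row["complete"] = breakdown.complete
            rows.append(row)
    columns = (
        ["mouse_id", "group", "time_h"]
        + [f"score_{name}" for name in ALL_ITEM_FIELDS]
        + ["mss_subtotal", "amss_total", "complete"]
    )
    frame = pd.DataFrame(rows, columns=columns)
    for col in columns[3:-1]:
        frame[col] = frame[col].astype("Int64")
    return frame


def classify(amss_total: float, cutoff: float = DEFAULT_CUTOFF) -> Classification:
    """Dichotomize an A-MSS total: septic iff strictly above the cutoff.

    A total exactly at the cutoff is non-septic; with integer totals and the
    default half-integer cutoff of 3.5 the boundary case never occurs.
    """
    _require_finite(cutoff, "cutoff")
    _require_finite(amss_total, "amss_total")
    return Classification.SEPTIC if amss_total > cutoff else Classification.NON_SEPTIC


# ---------------------------------------------------------------------------
# Rubric reference text
# ---------------------------------------------------------------------------

#: The full ten-item descriptor table (score 0..4 for each item), for human
#: reference and export.  The seven observational rows are the standard MSS
#: wording; the three quantitative rows state the bin boundaries.
RUBRIC: dict[str, tuple[str, str, str, str, str]] = {
    "Appearance": (
        "Coat is smooth",
        "Patches of hair piloerected",
        "Majority of back is piloerected",
        "Piloerection may or may not be present; mouse appears “puffy”",
        "Piloerection may or may not be present; mouse appears emaciated",
    ),
    "Level of consciousness": (
        "Mouse is active",
        "Mouse is active but avoids standing upright",
        "Mouse activity is noticeably slowed. The mouse is still ambulant",
        "Activity is impaired. Mouse only moves when provoked; movements have a tremor",
        "Activity severely impaired. Remains stationary when provoked, with possible tremor",
    ),
    "Activity": (
        "Normal amount of activity. Mouse is any of eating, drinking, climbing, running, and fighting",
        "Slightly suppressed activity. Mouse is moving around bottom of cage",
        "Suppressed activity. Mouse is stationary with occasional investigative movements",
        "No activity",
        "No activity. Mouse experiencing tremors, particularly in the hind legs",
    ),
    "Response to stimulus": (
        "Mouse responds immediately to auditory stimulus or touch",
        "Slow or no response to auditory stimulus; strong response to touch (moves to escape)",
        "No response to auditory stimulus; moderate response to touch (moves a few steps)",
        "No response to auditory stimulus; mild response to touch (no locomotion)",
        "No response to auditory stimulus. Little or no response to touch. Cannot right itself if pushed over",
    ),
    "Eyes": (
        "Open",
        "Eyes not fully open, possibly with secretions",
        "Eyes at least half closed, possibly with secretions",
        "Eyes half closed or more, possibly with secretions",
        "Eyes closed or milky",
    ),
    "Respiration rate": (
        "Normal, rapid mouse respiration",
        "Slightly decreased respiration (rate not quantifiable by the eye)",
        "Moderately reduced respiration (rate at the upper range of quantifying by the eye)",
        "Severely reduced respiration (rate easily countable by the eye, 0.5 s between breaths)",
        "Extremely reduced respiration (>1 s between breaths)",
    ),
    "Respiration quality": (
        "Normal",
        "Brief periods of laboured breathing",
        "Laboured, no gasping",
        "Laboured with intermittent gasps",
        "Gasping",
    ),
    "Rectal temperature (°C)": (
        "36-38",
        "> 38",
        "< 36- ≥ 35",
        "< 35- ≥ 34",
        "< 34",
    ),
    "Glycemia (mg/dL)": (
        "≥148",
        "≤148-≥122",
        "<122-≥58",
        "<58->40",
        "≤ 40",
    ),
    "Relative body weight loss (%)": (
        "0-5",
        "5-10",
        "10-15",
        "15-20",
        "> 20",
    ),
}


def rubric_markdown() -> str:
    """The ten-item rubric as a Markdown table (score columns 0-4)."""
    lines = [
        "| Item | 0 | 1 | 2 | 3 | 4 |",
        "| --- | --- | --- | --- | --- | --- |",
    ]
    for item, descriptors in RUBRIC.items():
        cells = " | ".join(descriptors)
        lines.append(f"| {item} | {cells} |")
    return "\n".join(lines) + "\n"
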