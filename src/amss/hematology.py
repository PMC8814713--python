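"""Derived hematological severity indices.

Sepsis perturbs the blood count in characteristic ways — early neutrophilia,
late lymphopenia and thrombocytopenia — and ratio indices built from the
panel (NLR, PLR, MPV/PC) track severity better than any single count.  This
module derives those indices from a :class:`HematologyPanel`, treating every
missing input as propagating to an *undefined* (not zero) index.

Counts are in units of 10^3 cells/uL and assumed already dilution-corrected;
MPV is in fL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import TYPE_CHECKING, Optional

import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .model import Cohort

__all__ = ["HematologyPanel", "DerivedIndices", "derive_indices", "index_timecourse"]

#: Fractional slack allowed when checking neut+lymph+mono against WBC
#: (rounding of the differential; unclassified cells may only make the sum
#: *smaller* than WBC, which is always acceptable).
_WBC_CONSISTENCY_TOL = 0.02


@dataclass(frozen=True)
class HematologyPanel:
    """A (possibly partial) blood count: total leukocytes, the differential,
    platelets, and mean platelet volume."""

    wbc: Optional[float] = None    # total white blood cells, 10^3/uL
    neut: Optional[float] = None   # neutrophils, 10^3/uL
    lymph: Optional[float] = None  # lymphocytes, 10^3/uL
    mono: Optional[float] = None   # monocytes, 10^3/uL
    plt: Optional[float] = None    # platelets, 10^3/uL
    mpv: Optional[float] = None    # mean platelet volume, fL

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            if not (math.isfinite(value) and value >= 0):
                raise ValidationError(
                    f"hematology field {f.name} must be finite and >= 0, got {value}"
                )
        if None not in (self.wbc, self.neut, self.lymph, self.mono):
            differential = self.neut + self.lymph + self.mono
            if differential > self.wbc * (1.0 + _WBC_CONSISTENCY_TOL):
                raise ValidationError(
                    f"differential sum {differential:.3g} exceeds WBC {self.wbc:.3g}"
                )


@dataclass(frozen=True)
class DerivedIndices:
    """Ratio indices derived from one panel.

    ``None`` means *undefined*; :attr:`flags` records why
    (``"missing_input"`` or ``"zero_denominator"``) for each undefined index.
    """

    nlr: Optional[float] = None               # neutrophil / lymphocyte
    plr: Optional[float] = None               # platelet / lymphocyte
    mpv_pc: Optional[float] = None            # MPV / platelet count, fL per 10^3/uL
    plt_relative_pct: Optional[float] = None  # platelets as % of baseline count
    flags: tuple[tuple[str, str], ...] = ()

    def flag(self, index: str) -> Optional[str]:
        return dict(self.flags).get(index)


def _ratio(numerator: Optional[float], denominator: Optional[float]):
    """(value, flag): value when both inputs present and denominator > 0."""
    if numerator is None or denominator is None:
        return None, "missing_input"
    if denominator == 0:
        return None, "zero_denominator"
    return numerator / denominator, None


def derive_indices(
    panel: HematologyPanel, baseline_plt: Optional[float] = None
) -> DerivedIndices:
    """Compute NLR, PLR, MPV/PC and the baseline-relative platelet percent.

    Each index is defined only when its inputs are present and its
    denominator is positive; a zero denominator yields an undefined index
    with an explicit flag rather than an exception.
    """
    flags: list[tuple[str, str]] = []
    values: dict[str, Optional[float]] = {}
    for name, num, den in (
        ("nlr", panel.neut, panel.lymph),
        ("plr", panel.plt, panel.lymph),
        ("mpv_pc", panel.mpv, panel.plt),
    ):
        value, flag = _ratio(num, den)
        values[name] = value
        if flag:
            flags.append((name, flag))
    rel, flag = _ratio(panel.plt, baseline_plt)
    values["plt_relative_pct"] = 100.0 * rel if rel is not None else None
    if flag:
        flags.append(("plt_relative_pct", flag))
    return DerivedIndices(flags=tuple(flags), **values)


def index_timecourse(cohort: "Cohort") -> pd.DataFrame:
    """Per-observation derived indices for every observation that carries a
    hematology panel.

    The baseline platelet count is each animal's earliest panel; returns a
    DataFrame with columns mouse_id, group, time_h, the four raw counts the
    indices use, and nlr/plr/mpv_pc/plt_relative_pct (NaN = undefined).
    Cohorts without hematology yield an empty table.
    """
    rows = []
    for record in cohort.records:
        baseline_plt = record.baseline_plt
        for obs in record.observations:
            if obs.hematology is None:
                continue
            idx = derive_indices(obs.hematology, baseline_plt=baseline_plt)
            rows.append(
                {
                    "mouse_id": record.mouse_id,
                    "group": record.group.value,
                    "time_h": obs.time_h,
                    "wbc": obs.hematology.wbc,
                    "neut": obs.hematology.neut,
                    "lymph": obs.hematology.lymph,
                    "plt": obs.hematology.plt,
                    "nlr": idx.nlr,
                    "plr": idx.plr,
                    "mpv_pc": idx.mpv_pc,
                    "plt_relative_pct": idx.plt_relative_pct,
                }
            )
    columns = [
        "mouse_id", "group", "time_h", "wbc", "neut", "lymph", "plt",
        "nlr", "plr", "mpv_pc", "plt_relative_pct",
    ]
    return pd.DataFrame(rows, columns=columns)
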