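"""Core domain model: longitudinal murine-cohort data and CSV I/O.

A :class:`Cohort` holds one :class:`MouseRecord` per animal; each record is
an ordered series of :class:`Observation` objects (one per monitoring
timepoint, typically 0/4/12/24 h after sepsis induction).  Every measured
field is optional — missing values are first-class and any quantity that
needs a missing input is *undefined*, never imputed.

The on-disk format is a flat UTF-8 CSV with one row per (mouse, timepoint);
see :data:`CSV_COLUMNS`.  Empty cells are missing values, never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .errors import ParseError, UndefinedValueError, ValidationError
from .hematology import HematologyPanel

__all__ = [
    "Group",
    "Observation",
    "MouseRecord",
    "Cohort",
    "ITEM_FIELDS",
    "CSV_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "relative_weight_loss",
]


class Group(str, Enum):
    """Experimental arm: saline-injected control or fecal-solution sepsis."""

    CONTROL = "control"
    SEPSIS = "sepsis"

    @classmethod
    def parse(cls, text: str) -> "Group":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown group {text!r}; expected 'control' or 'sepsis'"
            ) from None


#: The seven observational MSS items, in rubric order.
ITEM_FIELDS = (
    "item_appearance",
    "item_consciousness",
    "item_activity",
    "item_stimulus",
    "item_eyes",
    "item_resp_rate",
    "item_resp_quality",
)

_HEMATOLOGY_COLUMNS = {
    "wbc_10e3_ul": "wbc",
    "neut_10e3_ul": "neut",
    "lymph_10e3_ul": "lymph",
    "mono_10e3_ul": "mono",
    "plt_10e3_ul": "plt",
    "mpv_fl": "mpv",
}

#: Canonical CSV schema (header order).  Unknown extra columns are ignored
#: on read; empty cell = missing.
CSV_COLUMNS = (
    "mouse_id",
    "group",
    "time_h",
    "weight_g",
    "temp_c",
    "glycemia_mgdl",
    *ITEM_FIELDS,
    *_HEMATOLOGY_COLUMNS,
)

TEMP_BOUNDS_C = (20.0, 45.0)


@dataclass(frozen=True)
class Observation:
    """One animal at one timepoint: raw physiology, the seven rater-assigned
    observational item scores (each an integer 0-4), and optional hematology.
    """

    mouse_id: str
    group: Group
    time_h: float
    weight_g: Optional[float] = None
    temp_c: Optional[float] = None
    glycemia_mgdl: Optional[float] = None
    item_appearance: Optional[int] = None
    item_consciousness: Optional[int] = None
    item_activity: Optional[int] = None
    item_stimulus: Optional[int] = None
    item_eyes: Optional[int] = None
    item_resp_rate: Optional[int] = None
    item_resp_quality: Optional[int] = None
    hematology: Optional[HematologyPanel] = None

    def __post_init__(self) -> None:
        if not self.mouse_id:
            raise ValidationError("mouse_id must be non-empty")
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group.parse(str(self.group)))
        if not (math.isfinite(self.time_h) and self.time_h >= 0):
            raise ValidationError(
                f"mouse {self.mouse_id}: time_h must be finite and >= 0, got {self.time_h}"
            )
        if self.weight_g is not None and not (
            math.isfinite(self.weight_g) and self.weight_g > 0
        ):
            raise ValidationError(
                f"mouse {self.mouse_id} at {self.time_h} h: weight_g must be positive"
            )
        if self.temp_c is not None and not (
            TEMP_BOUNDS_C[0] <= self.temp_c <= TEMP_BOUNDS_C[1]
        ):
            raise ValidationError(
                f"mouse {self.mouse_id} at {self.time_h} h: temp_c {self.temp_c} "
                f"outside physical bounds {TEMP_BOUNDS_C}"
            )
        if self.glycemia_mgdl is not None and not (
            math.isfinite(self.glycemia_mgdl) and self.glycemia_mgdl > 0
        ):
            raise ValidationError(
                f"mouse {self.mouse_id} at {self.time_h} h: glycemia_mgdl must be positive"
            )
        for name in ITEM_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if isinstance(value, bool) or not isinstance(value, int):
                raise ValidationError(
                    f"mouse {self.mouse_id} at {self.time_h} h: {name} must be an "
                    f"integer 0-4, got {value!r}"
                )
            if not 0 <= value <= 4:
                raise ValidationError(
                    f"mouse {self.mouse_id} at {self.time_h} h: {name}={value} "
                    "outside the 0-4 rubric range"
                )

    def items(self) -> dict[str, Optional[int]]:
        """The seven observational item scores, by field name."""
        return {name: getattr(self, name) for name in ITEM_FIELDS}


@dataclass(frozen=True)
class MouseRecord:
    """Longitudinal follow-up of one animal (observations at strictly
    increasing timepoints; the earliest is the baseline)."""

    mouse_id: str
    group: Group
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group.parse(str(self.group)))
        object.__setattr__(self, "observations", tuple(self.observations))
        times = [o.time_h for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"mouse {self.mouse_id}: observation times must be strictly "
                f"increasing (at most one observation per timepoint), got {times}"
            )
        for obs in self.observations:
            if obs.mouse_id != self.mouse_id:
                raise ValidationError(
                    f"observation mouse_id {obs.mouse_id!r} != record {self.mouse_id!r}"
                )
            if obs.group != self.group:
                raise ValidationError(
                    f"mouse {self.mouse_id}: observation group {obs.group.value!r} "
                    f"!= record group {self.group.value!r}"
                )

    @property
    def baseline(self) -> Optional[Observation]:
        """The earliest observation (time zero in the study design)."""
        return self.observations[0] if self.observations else None

    @property
    def baseline_weight_g(self) -> Optional[float]:
        return self.baseline.weight_g if self.baseline else None

    @property
    def baseline_plt(self) -> Optional[float]:
        if self.baseline is None or self.baseline.hematology is None:
            return None
        return self.baseline.hematology.plt

    def at(self, time_h: float) -> Optional[Observation]:
        for obs in self.observations:
            if math.isclose(obs.time_h, time_h, rel_tol=0.0, abs_tol=1e-9):
                return obs
        return None


@dataclass
class Cohort:
    """A set of mouse records with free-form study metadata."""

    records: list[MouseRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.mouse_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate mouse_ids in cohort: {dupes}")

    def __iter__(self) -> Iterable[MouseRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_observations(self) -> int:
        return sum(len(r.observations) for r in self.records)

    def by_group(self, group: Group) -> list[MouseRecord]:
        return [r for r in self.records if r.group == group]

    def timepoints(self) -> list[float]:
        """Sorted union of observation times across all animals."""
        return sorted({o.time_h for r in self.records for o in r.observations})


def relative_weight_loss(record: MouseRecord, time_h: float) -> float:
    """Percent body-weight loss at ``time_h`` relative to the animal's
    baseline (earliest) weight.

    ``100 * (w_baseline - w_t) / w_baseline``; negative values mean weight
    gain.  Raises :class:`UndefinedValueError` if either weight is missing.
    """
    baseline_w = record.baseline_weight_g
    if baseline_w is None:
        raise UndefinedValueError(
            f"mouse {record.mouse_id}: baseline weight missing; relative loss undefined"
        )
    obs = record.at(time_h)
    if obs is None or obs.weight_g is None:
        raise UndefinedValueError(
            f"mouse {record.mouse_id}: weight at {time_h} h missing; relative loss undefined"
        )
    return 100.0 * (baseline_w - obs.weight_g) / baseline_w


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_float(cell: str, row: int, column: str) -> Optional[float]:
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {cell!r} as a number"
        ) from None
    if not math.isfinite(value):
        raise ParseError(f"row {row}, column {column!r}: non-finite value {cell!r}")
    return value


def _parse_item(cell: str, row: int, column: str) -> Optional[int]:
    value = _parse_float(cell, row, column)
    if value is None:
        return None
    if value != int(value):
        raise ParseError(
            f"row {row}, column {column!r}: item score must be an integer, got {cell!r}"
        )
    return int(value)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort from the canonical CSV schema.

    Unknown columns are ignored; group strings are case-insensitive; empty
    cells map to missing fields.  Raises :class:`ParseError` for malformed
    cells (naming row and column) and :class:`ValidationError` for schema or
    domain violations (missing required columns, duplicate (mouse, time),
    item scores outside 0-4).
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file (no header row)") from None
    required = ("mouse_id", "group", "time_h")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; "
            f"expected schema {list(CSV_COLUMNS)}"
        )

    per_mouse: dict[str, list[Observation]] = {}
    groups: dict[str, Group] = {}
    for idx, row in frame.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        mouse_id = str(row["mouse_id"]).strip()
        if not mouse_id:
            raise ValidationError(f"row {rownum}: empty mouse_id")
        group = Group.parse(str(row["group"]))
        time_h = _parse_float(str(row["time_h"]), rownum, "time_h")
        if time_h is None:
            raise ValidationError(f"row {rownum}: time_h is required")

        def cell(column: str) -> str:
            return str(row[column]).strip() if column in frame.columns else ""

        hema_kwargs = {
            attr: _parse_float(cell(col), rownum, col)
            for col, attr in _HEMATOLOGY_COLUMNS.items()
        }
        hematology = (
            HematologyPanel(**hema_kwargs)
            if any(v is not None for v in hema_kwargs.values())
            else None
        )
        obs = Observation(
            mouse_id=mouse_id,
            group=group,
            time_h=time_h,
            weight_g=_parse_float(cell("weight_g"), rownum, "weight_g"),
            temp_c=_parse_float(cell("temp_c"), rownum, "temp_c"),
            glycemia_mgdl=_parse_float(cell("glycemia_mgdl"), rownum, "glycemia_mgdl"),
            hematology=hematology,
            **{name: _parse_item(cell(name), rownum, name) for name in ITEM_FIELDS},
        )
        if groups.setdefault(mouse_id, group) != group:
            raise ValidationError(
                f"row {rownum}: mouse {mouse_id} appears in more than one group"
            )
        previous = per_mouse.setdefault(mouse_id, [])
        if any(math.isclose(o.time_h, time_h, abs_tol=1e-9) for o in previous):
            raise ValidationError(
                f"row {rownum}: duplicate observation for mouse {mouse_id} at {time_h} h"
            )
        previous.append(obs)

    records = [
        MouseRecord(
            mouse_id=mouse_id,
            group=groups[mouse_id],
            observations=tuple(sorted(obs_list, key=lambda o: o.time_h)),
        )
        for mouse_id, obs_list in per_mouse.items()
    ]
    return Cohort(records=records, metadata={"source": str(path)})


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    # repr of a float is the shortest string that round-trips exactly
    return repr(float(value))


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort to the canonical CSV schema.

    Missing fields become empty cells (never zeros); floats are written with
    round-trip precision so ``read_cohort_csv(write_cohort_csv(c)) == c``.
    """
    rows = []
    for record in cohort.records:
        for obs in record.observations:
            row = {
                "mouse_id": obs.mouse_id,
                "group": obs.group.value,
                "time_h": _fmt(obs.time_h),
                "weight_g": _fmt(obs.weight_g),
                "temp_c": _fmt(obs.temp_c),
                "glycemia_mgdl": _fmt(obs.glycemia_mgdl),
            }
            for name in ITEM_FIELDS:
                row[name] = _fmt(getattr(obs, name))
            panel = obs.hematology
            for col, attr in _HEMATOLOGY_COLUMNS.items():
                row[col] = _fmt(getattr(panel, attr)) if panel is not None else ""
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS), dtype=str)
    frame.to_csv(path, index=False, lineterminator="\n")


def cohort_from_observations(
    observations: Iterable[Observation], metadata: Optional[dict] = None
) -> Cohort:
    """Group a flat observation stream into per-mouse records (sorted by
    time within each mouse; mouse order follows first appearance)."""
    per_mouse: dict[str, list[Observation]] = {}
    for obs in observations:
        per_mouse.setdefault(obs.mouse_id, []).append(obs)
    records = [
        MouseRecord(
            mouse_id=mouse_id,
            group=obs_list[0].group,
            observations=tuple(sorted(obs_list, key=lambda o: o.time_h)),
        )
        for mouse_id, obs_list in per_mouse.items()
    ]
    return Cohort(records=records, metadata=dict(metadata or {}))
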