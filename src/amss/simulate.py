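"""Seeded synthetic two-arm sepsis cohorts.

No public animal-level dataset accompanies the fecal-induced-peritonitis
study design this package targets, so this module generates cohorts with
the qualitative dynamics reported for that model: the sepsis arm develops
hypoglycemia, hypothermia and progressive weight loss over 24 h, platelets
and lymphocytes fall, neutrophils peak at 12 h before returning toward
baseline, and the observational MSS items rise with a shared latent
severity.  The control arm fluctuates around baseline.

The generator is intentionally phenomenological — truncated-Gaussian noise
around piecewise-linear group trajectories, not a pathophysiological model.
Its purpose is to exercise the scoring and statistics pipeline, and its
defaults are package constants chosen to sit squarely inside the rubric
bins (e.g. sepsis glycemia ends in the <= 40 mg/dL band, temperature below
34 °C, weight loss around 15 %).

Determinism: one integer seed drives everything; each variable draws from
its own child stream (seed combined with a CRC-32 of the variable name), so
adding a variable never perturbs the others and equal (config, seed) pairs
give byte-identical CSV output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .hematology import HematologyPanel
from .model import Cohort, Group, ITEM_FIELDS, MouseRecord, Observation

__all__ = [
    "TrajectorySpec",
    "SeveritySpec",
    "SimulationConfig",
    "default_config",
    "null_config",
    "generate_cohort",
    "config_to_dict",
    "config_from_dict",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """One simulated variable.

    value(mouse i, time t) = baseline_i + control_drift_per_h * t
                             [+ sepsis_effect(t) if the mouse is septic]
                             + N(0, residual_sd),
    truncated to [lo, hi] and rounded to ``decimals`` (measurement
    precision).  ``sepsis_effect`` maps timepoints to additive deviations
    and is linearly interpolated at off-grid times; monotone declines
    (glycemia, temperature, weight, platelets, lymphocytes) and peaked
    shapes (the 12 h neutrophil surge) are both just tables here.
    """

    baseline_mean: float
    baseline_sd: float
    residual_sd: float
    control_drift_per_h: float = 0.0
    sepsis_effect: dict[float, float] = field(default_factory=dict)
    lo: Optional[float] = None
    hi: Optional[float] = None
    decimals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.residual_sd < 0:
            raise ValidationError("trajectory standard deviations must be >= 0")

    def effect_at(self, time_h: float) -> float:
        if not self.sepsis_effect:
            return 0.0
        times = np.array(sorted(self.sepsis_effect))
        values = np.array([self.sepsis_effect[t] for t in times])
        return float(np.interp(time_h, times, values))


@dataclass(frozen=True)
class SeveritySpec:
    """Latent disease severity driving the seven observational items.

    The sepsis arm follows ``levels`` (time -> severity on the 0-4 item
    scale, linearly interpolated); controls sit at zero.  Each item score is
    clamp(round(severity + offset_item + N(0, item_noise_sd)), 0, 4), which
    induces the inter-item correlation the MSS assumes.
    """

    levels: dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 4.0: 1.2, 12.0: 2.2, 24.0: 3.0}
    )
    item_noise_sd: float = 0.35
    item_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.item_noise_sd < 0:
            raise ValidationError("item_noise_sd must be >= 0")
        unknown = set(self.item_offsets) - set(ITEM_FIELDS)
        if unknown:
            raise ValidationError(f"unknown item offsets: {sorted(unknown)}")

    def level_at(self, time_h: float) -> float:
        if not self.levels:
            return 0.0
        times = np.array(sorted(self.levels))
        values = np.array([self.levels[t] for t in times])
        return float(np.interp(time_h, times, values))


def _default_trajectories() -> dict[str, TrajectorySpec]:
    return {
        # grams; ~15 % loss by 24 h in the sepsis arm
        "weight_g": TrajectorySpec(
            baseline_mean=25.0, baseline_sd=1.5, residual_sd=0.3,
            sepsis_effect={0.0: 0.0, 4.0: -0.8, 12.0: -2.0, 24.0: -3.75},
            lo=10.0, decimals=2,
        ),
        # °C; below the 34 °C band by 24 h
        "temp_c": TrajectorySpec(
            baseline_mean=37.2, baseline_sd=0.25, residual_sd=0.2,
            sepsis_effect={0.0: 0.0, 4.0: -1.5, 12.0: -2.5, 24.0: -4.0},
            lo=28.0, hi=42.0, decimals=1,
        ),
        # mg/dL; from the >= 148 band into the <= 40 band by 24 h
        "glycemia_mgdl": TrajectorySpec(
            baseline_mean=160.0, baseline_sd=8.0, residual_sd=6.0,
            sepsis_effect={0.0: 0.0, 4.0: -50.0, 12.0: -90.0, 24.0: -125.0},
            lo=10.0, decimals=0,
        ),
        # counts in 10^3/uL: 12 h neutrophil peak, then return toward baseline
        "neut": TrajectorySpec(
            baseline_mean=1.2, baseline_sd=0.3, residual_sd=0.25,
            sepsis_effect={0.0: 0.0, 4.0: 1.0, 12.0: 2.8, 24.0: 0.3},
            lo=0.0, decimals=2,
        ),
        # progressive lymphopenia
        "lymph": TrajectorySpec(
            baseline_mean=6.0, baseline_sd=0.8, residual_sd=0.4,
            sepsis_effect={0.0: 0.0, 4.0: -1.0, 12.0: -2.5, 24.0: -4.0},
            lo=0.1, decimals=2,
        ),
        "mono": TrajectorySpec(
            baseline_mean=0.5, baseline_sd=0.12, residual_sd=0.08,
            sepsis_effect={0.0: 0.0, 4.0: -0.05, 12.0: -0.15, 24.0: -0.3},
            lo=0.0, decimals=2,
        ),
        # unclassified leukocytes; WBC is derived as the differential sum
        # plus this component, which keeps the panel internally consistent
        "wbc_other": TrajectorySpec(
            baseline_mean=0.4, baseline_sd=0.1, residual_sd=0.08,
            lo=0.0, decimals=2,
        ),
        # platelets, 10^3/uL: thrombocytopenia by 24 h
        "plt": TrajectorySpec(
            baseline_mean=1100.0, baseline_sd=90.0, residual_sd=60.0,
            sepsis_effect={0.0: 0.0, 4.0: -150.0, 12.0: -350.0, 24.0: -600.0},
            lo=50.0, decimals=0,
        ),
        # mean platelet volume, fL: no sepsis effect within 24 h
        "mpv": TrajectorySpec(
            baseline_mean=5.5, baseline_sd=0.3, residual_sd=0.15,
            lo=3.0, hi=12.0, decimals=1,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated study."""

    n_control: int = 7
    n_sepsis: int = 8
    timepoints_h: tuple[float, ...] = (0.0, 4.0, 12.0, 24.0)
    seed: int = 0
    trajectories: dict[str, TrajectorySpec] = field(
        default_factory=_default_trajectories
    )
    severity: SeveritySpec = field(default_factory=SeveritySpec)
    include_hematology: bool = True

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_sepsis < 1:
            raise ValidationError("group sizes must be >= 1")
        times = tuple(float(t) for t in self.timepoints_h)
        object.__setattr__(self, "timepoints_h", times)
        if len(times) < 1 or times[0] != 0.0:
            raise ValidationError("timepoints must start at 0 h")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        missing = set(_default_trajectories()) - set(self.trajectories)
        if missing:
            raise ValidationError(f"missing trajectory spec(s): {sorted(missing)}")


def default_config(seed: int = 0) -> SimulationConfig:
    """The stated study design: control n=7 vs sepsis n=8 at 0/4/12/24 h,
    with the documented default trajectories and severity curve."""
    return SimulationConfig(seed=seed)


def null_config(seed: int = 0) -> SimulationConfig:
    """Same design and noise but zero sepsis effects everywhere — the two
    arms are exchangeable, so any diagnostic signal is a false positive."""
    base = default_config(seed=seed)
    trajectories = {
        name: replace(spec, sepsis_effect={})
        for name, spec in base.trajectories.items()
    }
    severity = replace(base.severity, levels={0.0: 0.0})
    return replace(base, trajectories=trajectories, severity=severity)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent per-variable stream keyed by the variable name, so the
    set of simulated variables can grow without perturbing existing ones."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _simulate_variable(
    spec: TrajectorySpec,
    is_sepsis: np.ndarray,
    times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n_mice = is_sepsis.size
    baselines = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(n_mice)
    noise = spec.residual_sd * rng.standard_normal((n_mice, times.size))
    effects = np.array([spec.effect_at(t) for t in times])
    values = (
        baselines[:, None]
        + spec.control_drift_per_h * times[None, :]
        + np.where(is_sepsis[:, None], effects[None, :], 0.0)
        + noise
    )
    if spec.lo is not None or spec.hi is not None:
        values = np.clip(values, spec.lo, spec.hi)
    if spec.decimals is not None:
        values = np.round(values, spec.decimals)
    return values


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort from a config; deterministic given ``config.seed``."""
    n_total = config.n_control + config.n_sepsis
    is_sepsis = np.array([False] * config.n_control + [True] * config.n_sepsis)
    mouse_ids = [f"C{i + 1}" for i in range(config.n_control)] + [
        f"S{i + 1}" for i in range(config.n_sepsis)
    ]
    times = np.array(config.timepoints_h)

    variables = {
        name: _simulate_variable(spec, is_sepsis, times, _stream(config.seed, name))
        for name, spec in config.trajectories.items()
    }

    item_rng = _stream(config.seed, "items")
    item_noise = config.severity.item_noise_sd * item_rng.standard_normal(
        (n_total, times.size, len(ITEM_FIELDS))
    )
    severity_levels = np.array([config.severity.level_at(t) for t in times])
    offsets = np.array(
        [config.severity.item_offsets.get(name, 0.0) for name in ITEM_FIELDS]
    )
    latent = (
        np.where(is_sepsis[:, None], severity_levels[None, :], 0.0)[:, :, None]
        + offsets[None, None, :]
        + item_noise
    )
    item_scores = np.clip(np.round(latent), 0, 4).astype(int)

    records = []
    for i, mouse_id in enumerate(mouse_ids):
        group = Group.SEPSIS if is_sepsis[i] else Group.CONTROL
        observations = []
        for j, t in enumerate(times):
            hematology = None
            if config.include_hematology:
                neut = variables["neut"][i, j]
                lymph = variables["lymph"][i, j]
                mono = variables["mono"][i, j]
                hematology = HematologyPanel(
                    wbc=round(neut + lymph + mono + variables["wbc_other"][i, j], 2),
                    neut=neut,
                    lymph=lymph,
                    mono=mono,
                    plt=variables["plt"][i, j],
                    mpv=variables["mpv"][i, j],
                )
            observations.append(
                Observation(
                    mouse_id=mouse_id,
                    group=group,
                    time_h=float(t),
                    weight_g=variables["weight_g"][i, j],
                    temp_c=variables["temp_c"][i, j],
                    glycemia_mgdl=variables["glycemia_mgdl"][i, j],
                    hematology=hematology,
                    **{
                        name: int(item_scores[i, j, k])
                        for k, name in enumerate(ITEM_FIELDS)
                    },
                )
            )
        records.append(
            MouseRecord(mouse_id=mouse_id, group=group, observations=tuple(observations))
        )
    metadata = {
        "generator": "amss.simulate",
        "seed": config.seed,
        "timepoints_h": list(config.timepoints_h),
    }
    return Cohort(records=records, metadata=metadata)


# ---------------------------------------------------------------------------
# Config (de)serialization for the CLI
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    out = asdict(config)
    out["timepoints_h"] = list(config.timepoints_h)
    for name, spec in out["trajectories"].items():
        spec["sepsis_effect"] = {str(k): v for k, v in spec["sepsis_effect"].items()}
    out["severity"]["levels"] = {
        str(k): v for k, v in out["severity"]["levels"].items()
    }
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    trajectories = {}
    for name, spec in data.get("trajectories", {}).items():
        spec = dict(spec)
        spec["sepsis_effect"] = {
            float(k): float(v) for k, v in spec.get("sepsis_effect", {}).items()
        }
        trajectories[name] = TrajectorySpec(**spec)
    if trajectories:
        data["trajectories"] = trajectories
    if "severity" in data:
        severity = dict(data["severity"])
        severity["levels"] = {
            float(k): float(v) for k, v in severity.get("levels", {}).items()
        }
        data["severity"] = SeveritySpec(**severity)
    if "timepoints_h" in data:
        data["timepoints_h"] = tuple(float(t) for t in data["timepoints_h"])
    return SimulationConfig(**data)
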