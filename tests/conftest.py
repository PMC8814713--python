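"""Shared fixtures: small deterministic cohorts, noise-free configs."""

from dataclasses import replace

import pytest

from amss.model import Cohort, Group, ITEM_FIELDS, MouseRecord, Observation
from amss.hematology import HematologyPanel
from amss.simulate import SimulationConfig, default_config, generate_cohort


def make_observation(
    mouse_id="M1",
    group=Group.CONTROL,
    time_h=0.0,
    weight_g=25.0,
    temp_c=37.0,
    glycemia_mgdl=160.0,
    items=0,
    hematology=None,
    **overrides,
):
    """An Observation with uniform item scores and sane physiology."""
    kwargs = dict(
        mouse_id=mouse_id,
        group=group,
        time_h=time_h,
        weight_g=weight_g,
        temp_c=temp_c,
        glycemia_mgdl=glycemia_mgdl,
        hematology=hematology,
    )
    kwargs.update({name: items for name in ITEM_FIELDS})
    kwargs.update(overrides)
    return Observation(**kwargs)


def make_panel(wbc=8.0, neut=1.2, lymph=6.0, mono=0.5, plt=1100.0, mpv=5.5):
    return HematologyPanel(wbc=wbc, neut=neut, lymph=lymph, mono=mono, plt=plt, mpv=mpv)


def noise_free_config(seed: int = 0) -> SimulationConfig:
    """Default trajectories with every noise source zeroed: controls are
    textbook-healthy, the sepsis arm follows the mean curves exactly."""
    base = default_config(seed=seed)
    trajectories = {
        name: replace(spec, baseline_sd=0.0, residual_sd=0.0)
        for name, spec in base.trajectories.items()
    }
    severity = replace(base.severity, item_noise_sd=0.0)
    return replace(base, trajectories=trajectories, severity=severity)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def noise_free_cohort() -> Cohort:
    return generate_cohort(noise_free_config(seed=1))


@pytest.fixture
def tiny_cohort() -> Cohort:
    """One control + one sepsis mouse, two timepoints, hand-built."""
    records = []
    for mouse_id, group, sick in (("C1", Group.CONTROL, False), ("S1", Group.SEPSIS, True)):
        obs = [
            make_observation(mouse_id=mouse_id, group=group, time_h=0.0,
                             hematology=make_panel()),
            make_observation(
                mouse_id=mouse_id, group=group, time_h=4.0,
                weight_g=22.0 if sick else 25.0,
                temp_c=34.5 if sick else 37.0,
                glycemia_mgdl=50.0 if sick else 160.0,
                items=2 if sick else 0,
                hematology=make_panel(neut=4.0, lymph=2.0) if sick else make_panel(),
            ),
        ]
        records.append(MouseRecord(mouse_id=mouse_id, group=group, observations=tuple(obs)))
    return Cohort(records=records)
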