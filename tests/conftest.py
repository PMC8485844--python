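"""Shared fixtures: synthetic trials at two sizes and their fitted surfaces."""

from __future__ import annotations

import dataclasses

import pytest

from ed50mcid.data_model import PHQ9, compute_changes
from ed50mcid.monotone_gamm import SmoothSpec, fit_gamm
from ed50mcid.synthetic_data import default_config, generate_trial, grc_mappings


def shrink(config, n_per_study):
    """Scale a trial config down to quick-test size, preserving structure."""
    studies = tuple(
        dataclasses.replace(block, n_patients=n)
        for block, n in zip(config.studies, n_per_study)
    )
    return dataclasses.replace(config, studies=studies)


@pytest.fixture(scope="session")
def small_trial():
    """~100-patient two-study PHQ-9 trial: (config, visits, records)."""
    config = shrink(default_config("PHQ9"), (60, 40))
    visits, _ = generate_trial(config)
    records = compute_changes(visits, PHQ9, grc_mappings(config))
    return config, visits, records


@pytest.fixture(scope="session")
def small_surface(small_trial):
    """Deterministic fixed-smoothing fit on the small trial."""
    _, _, records = small_trial
    spec = SmoothSpec(
        smoothing_selection="fixed",
        lambda_surface=1.0,
        lambda_baseline=1.0,
        fixed_sigma_u=0.5,
    )
    return fit_gamm(records, spec)


@pytest.fixture(scope="session")
def default_trial():
    """The full default two-study trial (800 patients): (config, records)."""
    config = default_config("PHQ9")
    visits, _ = generate_trial(config)
    records = compute_changes(visits, PHQ9, grc_mappings(config))
    return config, records


@pytest.fixture(scope="session")
def default_surface(default_trial):
    """REML fit of the monotone GAMM on the full default trial."""
    _, records = default_trial
    return fit_gamm(records)
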