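"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ffconcord.design import PM_MM, PM_ONLY
from ffconcord.simulate import (
    SimulationConfig,
    make_array_design,
    simulate_matched_experiment,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast 150-gene world with the full 5-dataset layout."""
    return SimulationConfig(seed=7, n_genes=150, n_de_genes=10, n_antigenomic=10)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_matched_experiment(small_cfg)


@pytest.fixture(scope="session")
def pm_only_design(small_cfg):
    return make_array_design(small_cfg, PM_ONLY)


@pytest.fixture(scope="session")
def pm_mm_design(small_cfg):
    return make_array_design(small_cfg, PM_MM)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
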