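"""Shared fixtures: cached fluence kernels, synthetic stopping tables, cells."""

import numpy as np
import pytest

from iondamage import (
    CellNucleus,
    DamageParams,
    FluenceModel,
    ion,
    make_synthetic_table,
)


@pytest.fixture(scope="session")
def carbon():
    return ion("12C")


@pytest.fixture(scope="session")
def carbon_table(carbon):
    """Synthetic Bethe stopping table spanning the full carbon LET range."""
    return make_synthetic_table(carbon, np.geomspace(0.05 * 12, 600 * 12, 60))


@pytest.fixture(scope="session")
def model_soft():
    """Fluence model with the weak-attenuation preset (gamma = 1e-4)."""
    return FluenceModel(1e-4)


@pytest.fixture(scope="session")
def model_hard():
    """Fluence model with the strong-attenuation preset (gamma = 1e-2)."""
    return FluenceModel(1e-2)


@pytest.fixture(scope="session")
def params_soft():
    return DamageParams.for_gamma(1e-4)


@pytest.fixture(scope="session")
def human_cell():
    return CellNucleus("human", An=172.3, Ng=3.2e9)
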