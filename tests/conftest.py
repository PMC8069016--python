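"""Shared fixtures: reference models, study design, small synthetic data."""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from rutinpk.design import default_design, simulate_study
from rutinpk.reference import iv_reference_model, oral_reference_model
from rutinpk.structural import ROUTE_IV, ROUTE_ORAL


@pytest.fixture(scope="session")
def iv_model():
    return iv_reference_model()


@pytest.fixture(scope="session")
def oral_model():
    return oral_reference_model()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def iv_design(design):
    return design.subset(routes=(ROUTE_IV,))


@pytest.fixture(scope="session")
def oral_design(design):
    return design.subset(routes=(ROUTE_ORAL,))


@pytest.fixture(scope="session")
def iv_study(iv_design, iv_model):
    """One simulated 25-rat IV study (fixed seed)."""
    return simulate_study(iv_design, iv_model, None, seed=42)


@pytest.fixture(scope="session")
def oral_study(oral_design, oral_model):
    """One simulated 25-rat oral study (fixed seed)."""
    return simulate_study(oral_design, None, oral_model, seed=42)


@pytest.fixture(scope="session")
def full_study(design, iv_model, oral_model):
    return simulate_study(design, iv_model, oral_model, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
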