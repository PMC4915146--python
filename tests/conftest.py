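"""Shared fixtures.

Expensive artefacts (the full-scale model, its wild-type batch trajectory,
the chemostat steady states) are session-scoped and shared across test
modules; everything is generated programmatically at test time.
"""

import numpy as np
import pytest

from ccmkin.ecoli import load_ecoli_model
from ccmkin.fixtures import exponential_model, monod_model, toy_model
from ccmkin.simulate import CultureConfig, simulate


@pytest.fixture(scope="session")
def ecoli():
    return load_ecoli_model()


@pytest.fixture(scope="session")
def wt_batch(ecoli):
    """WT batch trajectory, 0-10 h at 0.05 h (growth-phase window)."""
    grid = np.arange(0.0, 10.0001, 0.05)
    return simulate(ecoli, CultureConfig(t_span=(0.0, 10.0), output_grid=grid))


@pytest.fixture()
def toy():
    return toy_model()


@pytest.fixture()
def monod():
    return monod_model()


@pytest.fixture()
def expo():
    return exponential_model()

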