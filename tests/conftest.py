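"""Shared fixtures.

Heavy ensembles used by several acceptance-style checks (the gamma sweep and
the two equal-gamma parameterizations) are computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import cellmatch as cm
from cellmatch import experiments as ex
from cellmatch.geometry import TissueConfiguration, TypeLengthParams

#: 10% coefficient-of-variation geometry used by the statistical checks.
CV10 = {"S": TypeLengthParams(4.0, 0.4), "T": TypeLengthParams(5.0, 0.5)}

MASTER_SEED = 20_250_101 % 100_000  # fixed suite seed


@pytest.fixture(scope="session")
def master_seed() -> int:
    return MASTER_SEED


@pytest.fixture(scope="session")
def cv10_params():
    return CV10


@pytest.fixture(scope="session")
def cv10_factory():
    return ex.tissue_factory(length_params=CV10)


@pytest.fixture()
def small_config() -> TissueConfiguration:
    """Deterministic 2-cells-per-row S|T configuration at rest."""
    l0 = np.array([[1.0, 1.2], [1.0, 1.2]])
    vertices = np.zeros((2, 3))
    vertices[:, 1] = l0[:, 0]
    vertices[:, 2] = l0.sum(axis=1)
    types = np.array([[0, 1], [0, 1]], dtype=np.int8)
    return TissueConfiguration(vertices, types, l0)


@pytest.fixture(scope="session")
def wt_config() -> TissueConfiguration:
    return cm.make_tissue(length_params=CV10, rng=MASTER_SEED)


@pytest.fixture(scope="session")
def gamma_sweep_results(cv10_factory, master_seed):
    """Gamma grid ensembles (30 replicates each, N=52, CV 10%)."""
    return ex.sweep_gamma(
        gamma_grid=[0.0, 0.25, 0.5, 1.0, 2.0],
        config_factory=cv10_factory,
        settings=cm.MCMCSettings(),
        n_replicates=30,
        master_seed=master_seed,
    )


@pytest.fixture(scope="session")
def collapse_pair(cv10_factory, master_seed):
    """Two different epsilon splits with identical gamma = 2."""
    settings = cm.MCMCSettings()
    pA = cm.AdhesionParameters(eps_SS=1.5, eps_TT=0.5, eps_ST=0.0, K=1.0)
    pB = cm.AdhesionParameters(eps_SS=1.0, eps_TT=1.4, eps_ST=0.2, K=1.0)
    rA = ex.run_ensemble(cv10_factory, pA, settings, 30, master_seed)
    rB = ex.run_ensemble(cv10_factory, pB, settings, 30, master_seed)
    return rA, rB
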