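"""Shared fixtures: reference tables and session-scoped mock ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from reactoprobe.fixtures import reference_tables
from reactoprobe.synthetic import MockParams, mock_ensemble


@pytest.fixture(scope="session")
def tables():
    return reference_tables()


def study_mock_params(compound: str, tables, seed: int) -> MockParams:
    """Mock-ensemble parameters mirroring one compound's published summary.

    Reaction/fault probabilities follow the classification counts and the
    injected per-degree offset is sized so that, in expectation, the Eq.-10
    style estimator lands on the published ΔU' for that compound.
    """
    row = tables.classification[compound]
    xp_exact = row.reactive / (row.reactive + row.non_reactive)
    du_target = tables.delta[compound].delta_uprime
    ndeg = 3 * 1268 - 6
    return MockParams(
        n_traj=100,
        p_react=row.reactive / row.total,
        p_fault=row.faults / row.total,
        delta_per_deg=du_target / (xp_exact * ndeg),
        seed=seed,
    )


@pytest.fixture(scope="session")
def mock_c1(tables):
    """Compound-1-like mock ensemble (x_p ~ 0.07, ΔU' ~ -7.09), fixed seed."""
    params = study_mock_params("1", tables, seed=20231219)
    trajs, truths = mock_ensemble(params)
    return params, trajs, truths


@pytest.fixture(scope="session")
def mock_c2(tables):
    """Compound-2-like mock ensemble (x_p ~ 0.18, ΔU' ~ -11.59), fixed seed."""
    params = study_mock_params("2", tables, seed=20231219 + 1)
    trajs, truths = mock_ensemble(params)
    return params, trajs, truths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
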