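"""Shared fixtures: synthetic stores, assembled models, and a fixed-step
integrator oracle kept independent of the adaptive engine under test."""

from __future__ import annotations

import numpy as np
import pytest

from pathwaykit import builder, fixtures, network, stores
from pathwaykit.parameterise import parameterise


@pytest.fixture(scope="session")
def glyco_paths(tmp_path_factory):
    """Glycolysis-shaped fixture store files (12 ORFs, 11 reactions)."""
    out = tmp_path_factory.mktemp("glyco")
    fx = fixtures.glycolysis_fixture(out_dir=out, seed=0)
    return fx


@pytest.fixture(scope="session")
def glyco_store(glyco_paths):
    return network.load_network(glyco_paths["paths"]["network"])


@pytest.fixture(scope="session")
def glyco_model(glyco_store):
    return builder.assemble_model(
        glyco_store, orfs=fixtures.GLYCOLYSIS_ORFS,
        model_name="glycolysis (fixture)", model_id="glycolysis_fixture")


@pytest.fixture(scope="session")
def glyco_quant(glyco_paths, glyco_model):
    kstore = stores.load_kinetics(glyco_paths["paths"]["kinetics"])
    cstore = stores.load_key_results(glyco_paths["paths"]["key_results"])
    model, report = parameterise(glyco_model, kstore, cstore)
    return model, report


def rk4_integrate(rhs, x0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Classical fixed-step 4th-order Runge-Kutta; the brute-force oracle."""
    out = np.empty((len(t_grid), len(x0)))
    out[0] = x0
    x = np.array(x0, dtype=float)
    for i in range(1, len(t_grid)):
        t, h = t_grid[i - 1], t_grid[i] - t_grid[i - 1]
        k1 = rhs(t, x)
        k2 = rhs(t + h / 2, x + h / 2 * k1)
        k3 = rhs(t + h / 2, x + h / 2 * k2)
        k4 = rhs(t + h, x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = x
    return out
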