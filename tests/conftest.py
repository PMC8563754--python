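"""Shared fixtures: small seeded geometries and solved flow states."""

from __future__ import annotations

import numpy as np
import pytest

from chemocycle.config import RunConfig
from chemocycle.coupling import solve_coupled_flow
from chemocycle.tissue import build_domain


def reduced_config(seed: int = 20210, grid_n: int = 32) -> RunConfig:
    """Default study configuration at reduced grid resolution.

    The production grid is 64x64; unit and trend tests run at 32x32, which
    resolves the tumor rim and perivascular exchange while keeping a full
    protocol to a few seconds.
    """
    cfg = RunConfig()
    cfg.seed = seed
    cfg.domain.grid_n = grid_n
    return cfg


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return reduced_config()


@pytest.fixture(scope="session")
def default_network(default_cfg):
    return default_cfg.build_network()


@pytest.fixture(scope="session")
def default_grid(default_cfg):
    return default_cfg.build_grid()


@pytest.fixture(scope="session")
def default_flow(default_cfg):
    # solve on private copies so mutating tests cannot leak state
    net = default_cfg.build_network()
    grid = default_cfg.build_grid()
    flow = solve_coupled_flow(net, grid)
    return grid, flow


@pytest.fixture()
def small_grid():
    """8x8 grid over 2 mm with a 0.5 mm tumor disc (fast unit-test domain)."""
    return build_domain(tumor_radius=0.5e-3, extent=2e-3, h=2e-3 / 8)
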