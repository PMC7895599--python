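"""Shared fixtures.

Expensive steady-flow solves and the periodic flow tables for the
scaled-down 30 s perfusion study are session-scoped so every test module
reuses them.
"""

import numpy as np
import pytest

from stentflow import engine, hemodynamics, presets
from stentflow.scenario import SimulationConfig, build_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def empty_channel_cfg():
    return SimulationConfig(n_struts=0, domain_length=2.0, domain_height=0.5,
                            grid_spacing=0.025, duration=1.0)


@pytest.fixture(scope="session")
def empty_channel_steady(empty_channel_cfg):
    geo = build_geometry(empty_channel_cfg)
    flow = hemodynamics.steady_solve(empty_channel_cfg, geo,
                                     empty_channel_cfg.peak_inflow)
    return empty_channel_cfg, geo, flow


@pytest.fixture(scope="session")
def strut_steady():
    """Steady peak-inflow flow past one strut, no defect."""
    cfg = presets.single_strut_small(defects=False)
    geo = build_geometry(cfg)
    flow = hemodynamics.steady_solve(cfg, geo, cfg.peak_inflow)
    return cfg, geo, flow


@pytest.fixture(scope="session")
def defect_steady():
    """Steady peak-inflow flow past one strut with a tissue defect."""
    cfg = presets.single_strut_small(defects=True)
    geo = build_geometry(cfg)
    flow = hemodynamics.steady_solve(cfg, geo, cfg.peak_inflow)
    return cfg, geo, flow


@pytest.fixture(scope="session")
def small_flow_table():
    """Quasi-steady flow table for the fast single-strut scenario."""
    cfg = presets.single_strut_small(defects=False)
    return cfg, engine.compute_flow_table(cfg)
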