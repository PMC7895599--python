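"""Receptor-bond kinetics and tethered-platelet mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentflow.adhesion import (ADHERED, FREE, TETHERED, Bond, Platelet,
                                PlateletArrays, activate, advect_platelet,
                                attempt_tether_arrays, bond_force,
                                drag_coefficient, rupture_check_arrays,
                                update_tethered, update_tethered_arrays)
from stentflow.hemodynamics import FlowField
from stentflow.scenario import Grid, SimulationConfig, build_geometry


def make_uniform_flow(vy=0.0, vz=0.0, ny=40, nz=20, h=0.05, z0=0.0):
    """Unmasked 2-D flow field with constant velocity (test harness)."""
    grid = Grid(nx=1, ny=ny, nz=nz, h=h, x0=0.0, y0=0.0, z0=z0)
    solid = np.zeros(grid.shape, dtype=bool)
    f = FlowField.zeros(grid, solid)
    f.v[:] = vy
    f.w[:] = vz
    return f


def make_shear_flow(shear=10.0, ny=40, nz=40, h=0.05):
    """v = shear * z, w = 0 (linear wall shear)."""
    grid = Grid(nx=1, ny=ny, nz=nz, h=h, x0=0.0, y0=0.0, z0=0.0)
    solid = np.zeros(grid.shape, dtype=bool)
    f = FlowField.zeros(grid, solid)
    f.v[0] = shear * grid.zc[None, :]
    return f


def flat_wall_geometry():
    return build_geometry(SimulationConfig(n_struts=0))


# ----------------------------------------------------------------------
# Kelvin-Voigt bond force
# ----------------------------------------------------------------------

@settings(deadline=None, max_examples=60, derandomize=True)
@given(k=st.floats(1e-9, 1e-3), c=st.floats(0.0, 1e-6),
       x=st.floats(0.0, 50.0), v=st.floats(-50.0, 50.0),
       lam=st.floats(0.1, 10.0))
def test_bond_force_is_linear(k, c, x, v, lam):
    """Kelvin-Voigt superposition: F(lam*x, lam*v) = lam*F(x, v)."""
    b = Bond(anchor=np.zeros(3), spring_constant=k, damping=c,
             rest_length_um=1.0, formation_time=0.0)
    assert bond_force(b, lam * x, lam * v) == pytest.approx(
        lam * bond_force(b, x, v), rel=1e-9, abs=1e-30)


def test_bond_force_formula():
    b = Bond(anchor=np.zeros(3), spring_constant=1e-6, damping=1e-9,
             rest_length_um=1.0, formation_time=0.0)
    assert bond_force(b, 0.0, 0.0) == 0.0
    assert bond_force(b, 2.0, 1.0) == pytest.approx(2e-12 + 1e-15)
    # superposition: doubling both extension and rate doubles the force
    assert bond_force(b, 4.0, 2.0) == pytest.approx(2 * bond_force(b, 2.0, 1.0))


# ----------------------------------------------------------------------
# Tether formation statistics
# ----------------------------------------------------------------------

def _population_near_wall(n, z_mm, cfg):
    arr = PlateletArrays(n)
    arr.pos[:, 0] = 0.05
    arr.pos[:, 1] = np.linspace(0.1, 1.9, n) % 1.8 + 0.1
    arr.pos[:, 2] = z_mm
    arr.id[:] = np.arange(n)
    return arr


def test_tether_gap_gate():
    """No formation beyond the capture distance, certain formation in the
    strong-on-rate limit inside it."""
    cfg = SimulationConfig(n_struts=0, k_on=1e9)
    geo = flat_wall_geometry()
    rng = np.random.default_rng(0)
    far = _population_near_wall(2000, 0.0017, cfg)   # gap 0.7 um > 0.5 um
    attempt_tether_arrays(far, geo, cfg, 0.0, cfg.dt, rng)
    assert (far.state == FREE).all()
    near = _population_near_wall(2000, 0.0013, cfg)  # gap 0.3 um
    attempt_tether_arrays(near, geo, cfg, 0.0, cfg.dt, rng)
    assert (near.state == TETHERED).all()


def test_tether_frequency_matches_exponential():
    """Empirical tether frequency = 1 - exp(-k_on dt) over 1e5 trials."""
    kon_dt = 0.5
    cfg = SimulationConfig(n_struts=0, k_on=kon_dt / 0.01)
    geo = flat_wall_geometry()
    rng = np.random.default_rng(11)
    n = 100_000
    arr = _population_near_wall(n, 0.0012, cfg)
    attempt_tether_arrays(arr, geo, cfg, 0.0, cfg.dt, rng)
    p_exp = 1.0 - np.exp(-kon_dt)
    freq = (arr.state == TETHERED).mean()
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(freq - p_exp) < 3 * se


def test_tether_records_anchor_on_surface():
    cfg = SimulationConfig(n_struts=0, k_on=1e9)
    geo = flat_wall_geometry()
    arr = _population_near_wall(100, 0.0012, cfg)
    attempt_tether_arrays(arr, geo, cfg, 0.5, cfg.dt, np.random.default_rng(1))
    assert np.allclose(arr.anchor[:, 2], 0.0)
    assert np.allclose(arr.bond_t0, 0.5)


# ----------------------------------------------------------------------
# Rupture statistics (Bell model)
# ----------------------------------------------------------------------

def _bonded_population(n, koff0, state=TETHERED):
    arr = PlateletArrays(n)
    arr.pos[:, 2] = 0.001
    arr.state[:] = state
    arr.active[:] = state == ADHERED
    arr.bond_k[:] = 1e-6
    arr.bond_koff0[:] = koff0
    arr.bond_rest[:] = 0.001
    arr.bond_patch[:] = 0
    return arr


def test_rupture_frequency_matches_exponential():
    """Rupture frequency = 1 - exp(-k_off dt) within 3 SE over 1e5 bonds."""
    cfg = SimulationConfig()
    n = 100_000
    koff_dt = 0.2
    arr = _bonded_population(n, koff_dt / cfg.dt)
    forces = np.zeros(n)
    broke, _ = rupture_check_arrays(arr, cfg, cfg.dt, np.random.default_rng(2),
                                    forces)
    p_exp = 1.0 - np.exp(-koff_dt)
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(broke.size / n - p_exp) < 3 * se
    assert (arr.state[broke] == FREE).all()


def test_zero_offrate_never_ruptures():
    cfg = SimulationConfig()
    arr = _bonded_population(5000, 0.0)
    broke, _ = rupture_check_arrays(arr, cfg, cfg.dt, np.random.default_rng(3),
                                    np.zeros(5000))
    assert broke.size == 0


def test_bell_force_doubles_offrate():
    """Raising the force by F_c ln 2 doubles the off-rate (empirically)."""
    cfg = SimulationConfig()
    n = 200_000
    koff0 = 2.0
    f1 = np.full(n, 0.5 * cfg.rupture_force)
    f2 = f1 + cfg.rupture_force * np.log(2.0)
    rates = []
    for forces in (f1, f2):
        arr = _bonded_population(n, koff0)
        broke, _ = rupture_check_arrays(arr, cfg, cfg.dt, np.random.default_rng(4),
                                        forces)
        # invert the per-step probability back to a hazard
        p = broke.size / n
        rates.append(-np.log(1 - p) / cfg.dt)
    assert rates[1] / rates[0] == pytest.approx(2.0, rel=0.05)


def test_mean_bond_lifetime():
    """Mean lifetime converges to 1/k_off(F) over 1e4 bonds."""
    cfg = SimulationConfig()
    koff = 2.0
    n = 10_000
    arr = _bonded_population(n, koff)
    rng = np.random.default_rng(5)
    alive_since = np.zeros(n)
    lifetimes = np.full(n, np.nan)
    t = 0.0
    for _ in range(4000):
        forces = np.zeros(len(arr))
        broke, _ = rupture_check_arrays(arr, cfg, cfg.dt, rng, forces)
        t += cfg.dt
        newly = broke[np.isnan(lifetimes[broke])]
        lifetimes[newly] = t - alive_since[newly]
        arr.state[:] = TETHERED  # re-arm so indexing stays aligned
        arr.bond_koff0[:] = np.where(np.isnan(lifetimes), koff, 0.0)
        if not np.isnan(lifetimes).any():
            break
    assert not np.isnan(lifetimes).any()
    se = lifetimes.std() / np.sqrt(n)
    assert abs(lifetimes.mean() - 1.0 / koff) < 3 * se + 0.5 * cfg.dt


def test_firm_adhesion_limit_never_detaches():
    """With alpha -> infinity, adhered platelets survive any finite run."""
    cfg = SimulationConfig(activation_multiplier=1e12)
    arr = _bonded_population(1000, 5.0, state=TETHERED)
    from stentflow.adhesion import activate_arrays
    activate_arrays(arr, cfg, 1.0)
    assert (arr.state == ADHERED).all()
    rng = np.random.default_rng(6)
    for _ in range(1000):
        broke, _ = rupture_check_arrays(arr, cfg, cfg.dt, rng, np.zeros(1000))
        assert broke.size == 0


# ----------------------------------------------------------------------
# Activation
# ----------------------------------------------------------------------

def test_activation_scales_constants_and_is_idempotent():
    cfg = SimulationConfig(activation_multiplier=10.0)
    b = Bond(anchor=np.array([0.0, 0.5, 0.0]), spring_constant=1e-6,
             damping=1e-9, rest_length_um=1.0, formation_time=0.0,
             off_rate0=5.0)
    p = Platelet(position=np.array([0.0, 0.5, 0.001]), state=TETHERED, bond=b)
    q = activate(p, cfg)
    assert q.state == ADHERED and q.activated
    assert q.bond.spring_constant == pytest.approx(1e-5)
    assert q.bond.off_rate0 == pytest.approx(0.5)
    q2 = activate(q, cfg)
    assert q2.bond.spring_constant == pytest.approx(1e-5)
    assert q2.state == ADHERED


def test_activation_noop_on_free():
    p = Platelet(position=np.zeros(3))
    assert activate(p) is p


# ----------------------------------------------------------------------
# Transport
# ----------------------------------------------------------------------

def test_advect_uniform_flow_exact():
    flow = make_uniform_flow(vy=3.0, vz=-1.0)
    p = Platelet(position=np.array([0.0, 0.5, 0.5]))
    q = advect_platelet(p, flow, 0.01)
    np.testing.assert_allclose(q.position, [0.0, 0.5 + 0.03, 0.5 - 0.01],
                               atol=1e-12)


def test_advect_zero_flow_stationary():
    flow = make_uniform_flow()
    p = Platelet(position=np.array([0.0, 0.7, 0.3]))
    q = advect_platelet(p, flow, 0.01)
    np.testing.assert_allclose(q.position, p.position, atol=1e-15)


def test_advect_shear_matches_fine_reference():
    """100 coarse RK2 steps vs a dt/100 reference in a linear shear field."""
    flow = make_shear_flow(shear=10.0)
    dt = 0.01
    p = Platelet(position=np.array([0.0, 0.2, 0.8]))
    coarse = p
    for _ in range(100):
        coarse = advect_platelet(coarse, flow, dt)
    fine = p
    for _ in range(10_000):
        fine = advect_platelet(fine, flow, dt / 100)
    assert np.linalg.norm(coarse.position - fine.position) < 1e-3


# ----------------------------------------------------------------------
# Tethered mechanics
# ----------------------------------------------------------------------

def test_tethered_relaxes_toward_anchor_in_still_fluid():
    cfg = SimulationConfig()
    flow = make_uniform_flow()
    b = Bond(anchor=np.array([0.0, 0.5, 0.0]), spring_constant=1e-6,
             damping=1e-9, rest_length_um=1.0, formation_time=0.0,
             off_rate0=5.0)
    p = Platelet(position=np.array([0.0, 0.5, 0.0015]), state=TETHERED, bond=b)
    exts = []
    for _ in range(10):
        p = update_tethered(p, flow, cfg.dt, cfg)
        exts.append(np.linalg.norm(p.position - b.anchor) - 0.001)
    assert all(np.diff(exts) <= 1e-12)
    assert exts[-1] < exts[0]


def test_tethered_steady_extension_is_force_balance():
    """Constant drag: x* = F_drag / k, with F_drag = 6 pi mu a u."""
    cfg = SimulationConfig()
    u = 0.5  # mm/s constant streamwise flow
    flow = make_uniform_flow(vy=u)
    arr = PlateletArrays(1)
    arr.pos[0] = [0.0, 0.5012, 0.0]   # extended along +y from the anchor
    arr.state[0] = TETHERED
    arr.anchor[0] = [0.0, 0.5, 0.0]
    arr.bond_k[0] = 1e-6
    arr.bond_c[0] = 1e-9
    arr.bond_koff0[0] = 0.0
    arr.bond_rest[0] = 0.001
    for _ in range(200):
        forces = update_tethered_arrays(arr, flow, cfg, cfg.dt)
    gamma = drag_coefficient(cfg)
    x_star = gamma * (u * 1e-3) / 1e-6          # m
    ext = np.linalg.norm(arr.pos[0] - arr.anchor[0]) * 1e-3 - 1e-6
    assert ext == pytest.approx(x_star, rel=0.01)
    assert forces[0] == pytest.approx(gamma * u * 1e-3, rel=0.01)


def test_stokes_drag_oracle():
    """Drag for a 1 um platelet in a 10/s shear at 1 um above the wall."""
    cfg = SimulationConfig()
    gamma = drag_coefficient(cfg)
    u = 10.0 * 1e-6                    # m/s at z = 1 um
    expected = 6 * np.pi * 1.004e-3 * 1e-6 * u
    assert gamma * u == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1.8925e-16, rel=0.01)


def test_platelet_state_invariants():
    with pytest.raises(ValueError):
        Platelet(state=TETHERED)      # bonded state without a bond
    with pytest.raises(ValueError):
        Platelet(state=ADHERED,
                 bond=Bond(anchor=np.zeros(3), spring_constant=1e-6,
                           damping=0.0, rest_length_um=1.0,
                           formation_time=0.0))  # adhered but not activated
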