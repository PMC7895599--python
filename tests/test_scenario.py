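"""Scenario generation: geometry, waveform, seeding, masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stentflow.scenario import (InvalidGeometryError, SimulationConfig,
                                build_geometry, build_grid, inflow_profile,
                                seed_platelets, solid_mask)

D = 0.09144
R = D / 2


def test_strut_dimensions_half_buried():
    """Round struts of diameter 0.09144 mm, half embedded in the wall."""
    cfg = SimulationConfig()
    geo = build_geometry(cfg)
    assert geo.strut_radius == pytest.approx(0.04572)
    # exposed cap height above the wall plane equals the radius
    h = geo.local_wall_height(np.array([cfg.first_strut_y]))
    assert h[0] == pytest.approx(0.04572)
    assert geo.n_struts == 2


def test_no_struts_plain_channel():
    cfg = SimulationConfig(n_struts=0)
    geo = build_geometry(cfg)
    assert geo.n_struts == 0
    assert not geo.defects_present
    y = np.linspace(0, cfg.domain_length, 50)
    assert not geo.is_solid(y, np.full_like(y, 0.01)).any()


def test_defect_cavity_footprint_and_depth():
    """Defect width equals the strut diameter; cavity is carved tissue."""
    cfg = SimulationConfig(defects_present=True)
    geo = build_geometry(cfg)
    assert geo.defect_width == pytest.approx(D)
    assert geo.cavity_halfwidth == pytest.approx(R + D)
    yc = geo.strut_y[0]
    # point adjacent to the strut at z = -d/4: fluid with defects,
    # solid tissue without
    y_pt, z_pt = yc + R + 0.01, -D / 4
    assert geo.in_cavity(np.array([y_pt]), np.array([z_pt]))[0]
    assert not geo.is_solid(np.array([y_pt]), np.array([z_pt]))[0]
    geo0 = build_geometry(SimulationConfig())
    assert geo0.is_solid(np.array([y_pt]), np.array([z_pt]))[0]


def test_overlapping_struts_rejected():
    with pytest.raises(InvalidGeometryError):
        SimulationConfig(strut_spacing=0.5 * D)


@pytest.mark.parametrize("t,expected", [
    (0.0, 0.0),
    (0.5, 11.25),           # mid-ramp: linear
    (0.999999, 22.5 * 0.999999),  # just before the ramp completes
    (1.0, 0.0),
])
def test_inflow_sawtooth(t, expected):
    cfg = SimulationConfig(waveform_period=1.0)
    assert inflow_profile(t, cfg) == pytest.approx(expected, abs=1e-9)


def test_inflow_ramp_spans_default_period():
    cfg = SimulationConfig()
    assert inflow_profile(0.0, cfg) == 0.0
    assert inflow_profile(cfg.waveform_period / 2, cfg) == pytest.approx(11.25)
    assert inflow_profile(cfg.waveform_period * 0.999999, cfg) == pytest.approx(
        22.5, rel=1e-4)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(t=st.floats(0.0, 300.0, allow_nan=False),
       period=st.floats(0.05, 60.0, allow_nan=False),
       peak=st.floats(0.0, 100.0, allow_nan=False))
def test_inflow_bounded_and_periodic(t, period, peak):
    """The waveform stays within [0, peak] and repeats every period."""
    cfg = SimulationConfig(waveform_period=period, peak_inflow=peak)
    v = float(inflow_profile(t, cfg))
    assert 0.0 <= v <= peak + 1e-9
    assert float(inflow_profile(t + period, cfg)) == pytest.approx(v, abs=max(peak, 1.0) * 1e-7)


def test_inflow_periodicity():
    cfg = SimulationConfig(waveform_period=1.0)
    t = np.linspace(0, 3.0, 301)
    np.testing.assert_allclose(inflow_profile(t, cfg),
                               inflow_profile(t + cfg.waveform_period, cfg),
                               atol=1e-12)


def test_seed_count_matches_density(rng):
    """300e6/ml = 3e5 per mm^3: Poisson count over a 1 mm^3 fluid volume."""
    cfg = SimulationConfig(n_struts=0, domain_length=10.0, domain_height=2.0,
                           slab_thickness=0.05)
    geo = build_geometry(cfg)
    vol = geo.fluid_volume(cfg.domain_length, cfg.domain_height, cfg.thickness)
    assert vol == pytest.approx(1.0)
    pts = seed_platelets(cfg, geo, rng)
    lam = 3.0e5
    assert abs(len(pts) - lam) < 5 * np.sqrt(lam)


def test_seed_zero_volume_empty(rng):
    cfg = SimulationConfig(n_struts=0, domain_length=1.0, domain_height=1.0)
    geo = build_geometry(cfg)
    geo_vol = geo.fluid_volume(0.0, 1.0, cfg.thickness)
    assert geo_vol == 0.0
    # emulate a zero-volume channel by zero thickness domain length
    cfg2 = cfg.replace(platelet_density=1.0)  # near-empty draw
    pts = seed_platelets(cfg2, geo, np.random.default_rng(0))
    assert pts.shape[1] == 3


def test_seed_uniformity_chisquare():
    """Seeded positions are uniform: chi-square over 10x10x10 bins."""
    cfg = SimulationConfig(n_struts=0, mode="3d", domain_width=1.0,
                           domain_length=1.0, domain_height=1.0,
                           platelet_density=1.0e8, grid_spacing=0.05)
    geo = build_geometry(cfg)
    rng = np.random.default_rng(7)
    pts = seed_platelets(cfg, geo, rng)
    assert len(pts) > 9e4
    H, _ = np.histogramdd(pts, bins=(10, 10, 10),
                          range=((0, 1), (0, 1), (0, 1)))
    chi2, p = stats.chisquare(H.ravel())
    assert p > 0.001


def test_seeded_positions_never_solid(rng):
    cfg = SimulationConfig(defects_present=True, platelet_density=2e8,
                           domain_length=4.0, domain_height=0.5,
                           slab_thickness=0.05)
    geo = build_geometry(cfg)
    pts = seed_platelets(cfg, geo, rng)
    assert len(pts) > 1e4
    assert not geo.is_solid(pts[:, 1], pts[:, 2]).any()


def test_solid_mask_oracle_points():
    cfg = SimulationConfig(defects_present=True, domain_length=4.0,
                           domain_height=0.5)
    geo = build_geometry(cfg)
    grid = build_grid(cfg, geo)
    mask = solid_mask(geo, grid)
    yc = geo.strut_y[0]
    j = int((yc - grid.y0) / grid.h)
    k = int((0.0 - grid.z0) / grid.h)
    assert mask[0, j, k]  # strut center is solid
    assert not mask[0, j, -1]  # top of channel is fluid
    # below-floor tissue is solid
    k_floor = int((-geo.defect_depth - grid.h - grid.z0) / grid.h)
    assert mask[0, 2, max(k_floor, 0)]


def test_defects_only_remove_tissue():
    """On the same grid, defects can only reduce the solid-cell count."""
    base = SimulationConfig(domain_length=4.0, domain_height=0.5)
    wet = base.replace(defects_present=True)
    geo0, geo1 = build_geometry(base), build_geometry(wet)
    grid = build_grid(wet, geo1)
    assert solid_mask(geo1, grid).sum() <= solid_mask(geo0, grid).sum()


def test_geometry_and_seeding_deterministic():
    cfg = SimulationConfig(defects_present=True)
    g1, g2 = build_geometry(cfg), build_geometry(cfg)
    np.testing.assert_array_equal(g1.strut_y, g2.strut_y)
    p1 = seed_platelets(cfg, g1, np.random.default_rng(3))
    p2 = seed_platelets(cfg, g2, np.random.default_rng(3))
    np.testing.assert_array_equal(p1, p2)


def test_grid_requires_strut_resolution():
    cfg = SimulationConfig(grid_spacing=0.05)
    with pytest.raises(ValueError, match="too coarse"):
        build_grid(cfg, build_geometry(cfg))


def test_config_yaml_roundtrip(tmp_path):
    cfg = SimulationConfig(defects_present=True, rng_seed=42,
                           slab_thickness=0.07)
    path = tmp_path / "scenario.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == cfg


def test_config_invariants():
    with pytest.raises(ValueError):
        SimulationConfig(dt=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(activation_multiplier=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(parcel_weight=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(duration=-1.0)


def test_nearest_surface_gap_oracle():
    """Nearest-surface distances agree with hand-computed geometry."""
    cfg = SimulationConfig(defects_present=True, n_struts=1,
                           first_strut_y=1.5, domain_length=4.0)
    geo = build_geometry(cfg)
    yc = geo.strut_y[0]
    # directly above the strut crest
    d, ay, az, lab = geo.nearest_surface(np.array([yc]), np.array([R + 0.01]))
    assert d[0] == pytest.approx(0.01, abs=1e-12)
    from stentflow.scenario import PATCH_STRUT
    assert lab[0] == PATCH_STRUT
    # above intact wall far away
    d, ay, az, lab = geo.nearest_surface(np.array([0.2]), np.array([0.03]))
    assert d[0] == pytest.approx(0.03)
    assert az[0] == 0.0
    # inside the cavity, near the floor
    zq = -geo.defect_depth + 0.004
    yq = yc + geo.strut_radius + geo.defect_width * 0.75
    d, ay, az, lab = geo.nearest_surface(np.array([yq]), np.array([zq]))
    from stentflow.scenario import PATCH_DEFECT
    assert lab[0] == PATCH_DEFECT
    assert d[0] <= 0.004 + 1e-9 + min(
        geo.cavity_halfwidth + yc - yq, 1.0)  # floor is the closest patch
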