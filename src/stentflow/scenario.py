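"""Scenario generation: configuration, geometry, grid and platelet seeding.

This module builds the simulated world for every downstream stage: a
near-wall channel patch of a 3 mm vessel, an array of round stent struts
half-buried in the wall (optionally surrounded by tissue-defect cavities),
the pulsatile inflow waveform, and a uniformly seeded platelet population.

Coordinate convention: ``y`` is streamwise, ``z`` wall-normal with the intact
wall surface at ``z = 0`` and fluid occupying ``z > 0`` (defect cavities dip
below zero); ``x`` is transverse, parallel to the strut axes.  All lengths
are in mm, times in s, speeds in mm/s unless a field name says otherwise.
"""

from __future__ import annotations

import dataclasses

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

# Surface patch labels.
PATCH_WALL = 0      # injured vessel wall (exposed subendothelium, stented segment)
PATCH_DEFECT = 1    # tissue-defect cavity surface
PATCH_STRUT = 2     # strut metal
PATCH_HEALTHY = 3   # intact endothelium outside the stented segment

PATCH_NAMES = {PATCH_WALL: "injured_wall",
               PATCH_DEFECT: "defect_cavity",
               PATCH_STRUT: "strut_metal",
               PATCH_HEALTHY: "healthy_wall"}


class InvalidGeometryError(ValueError):
    """Raised when a configuration describes an impossible geometry."""


@dataclass
class SimulationConfig:
    """All physical and numerical parameters of a simulation run.

    Geometric and hemodynamic defaults follow the reference setup: a 3 mm
    vessel carrying pulsatile flow ramping linearly 0 -> 22.5 mm/s each
    period, round struts of diameter 0.09144 mm half-buried in the wall,
    optional peri-strut tissue defects of width equal to the strut diameter,
    platelets at 300e6/ml, coupling step 0.01 s, 30 s perfusion.  The
    receptor-bond closure constants (k_on, k_off0, spring/damper, rupture
    force scale, activation multiplier) are not fixed by any measurement
    available here; they are calibrated through :func:`stentflow.engine.calibrate`.
    """

    # --- vessel / strut / defect geometry (mm) ---
    vessel_diameter: float = 3.0
    strut_diameter: float = 0.09144
    n_struts: int = 2
    strut_spacing: float = 0.5          # center-to-center, streamwise
    first_strut_y: float = 1.5          # streamwise position of first strut center
    defects_present: bool = False
    defect_width: float | None = None   # None -> strut_diameter
    defect_depth: float | None = None   # None -> strut_diameter / 2

    # --- blood and flow ---
    blood_density: float = 1000.0       # kg/m^3
    dynamic_viscosity: float = 1.004e-3  # Pa s  (nu = mu/rho = 1.004e-6 m^2/s)
    peak_inflow: float = 22.5           # mm/s, sawtooth peak (section mean speed)
    waveform_period: float = 30.0       # s, one linear 0 -> peak ramp
    inflow_shape: str = "poiseuille"    # "poiseuille" (developed) or "plug"
    flow_model: str = "quasi_steady"    # or "unsteady"
    n_flow_levels: int = 12             # inflow ladder for the quasi-steady table

    # --- platelets ---
    platelet_density: float = 3.0e8     # per ml
    platelet_radius_um: float = 1.0
    parcel_weight: float = 1.0          # physical platelets per computational parcel
    brownian_motion: bool = True        # thermal diffusion of free platelets
    temperature_K: float = 310.0

    # --- discretization / domain (near-wall channel patch) ---
    mode: str = "2d"                    # "2d" (y-z slice) or "3d"
    grid_spacing: float = 0.01524       # mm, = strut_diameter / 6
    domain_length: float = 4.0          # mm, streamwise (y)
    domain_height: float = 1.5          # mm, wall-normal fluid height (z > 0)
    domain_width: float = 2.0           # mm, transverse (x), 3-D mode only
    slab_thickness: float = 0.1         # mm, represented x-thickness in 2-D mode
    dt: float = 0.01                    # s, flow/platelet coupling step
    duration: float = 30.0              # s
    cfl: float = 0.4
    spinup_periods: int = 1

    # --- adhesion closure constants (configurable, calibrated) ---
    k_on: float = 100.0                 # 1/s, tether on-rate at unit reactivity
    kon_scale: float = 1.0              # calibration multiplier on k_on
    shear_gated_tethering: bool = True  # on-rate scales with U(t)/U_peak
    capture_distance_um: float = 0.5    # gap gate for tether formation
    spring_constant: float = 1.0e-6     # N/m, Kelvin-Voigt spring
    damping: float = 1.0e-9             # N s/m, Kelvin-Voigt damper
    bond_rest_length_um: float = 1.0
    k_off0: float = 5.0                 # 1/s, unstressed off-rate
    rupture_force: float = 2.0e-11      # N, Bell force scale F_c
    activation_multiplier: float = 1000.0  # alpha >= 1 (firm adhesion)
    activation_delay: float = 0.0       # s after tethering
    wall_reactivity: float = 1.0
    defect_reactivity: float = 1.0
    strut_reactivity: float = 0.1
    # streamwise extent of the injured (reactive) wall segment around the
    # strut array, also the default counting region, in strut diameters
    region_upstream_diameters: float = 1.0
    region_downstream_diameters: float = 5.0
    monolayer_packing_um2: float = 4.0  # wall footprint area per adhered platelet
    count_tethered: bool = False        # include TETHERED in reported densities

    # --- bookkeeping ---
    rng_seed: int = 0
    record_interval: float = 0.1        # s, adhered-density sampling
    snapshot_times: tuple = (1.0, 3.0, 10.0, 30.0)

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            ("vessel_diameter", self.vessel_diameter),
            ("strut_diameter", self.strut_diameter),
            ("blood_density", self.blood_density),
            ("dynamic_viscosity", self.dynamic_viscosity),
            ("waveform_period", self.waveform_period),
            ("platelet_density", self.platelet_density),
            ("platelet_radius_um", self.platelet_radius_um),
            ("grid_spacing", self.grid_spacing),
            ("domain_length", self.domain_length),
            ("domain_height", self.domain_height),
            ("slab_thickness", self.slab_thickness),
            ("dt", self.dt),
        ]
        for name, val in positive:
            if not val > 0:
                raise ValueError(f"{name} must be > 0, got {val!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.n_struts < 0:
            raise ValueError("n_struts must be >= 0")
        if self.peak_inflow < 0:
            raise ValueError("peak_inflow must be >= 0")
        if self.activation_multiplier < 1:
            raise ValueError("activation_multiplier must be >= 1")
        if self.parcel_weight < 1:
            raise ValueError("parcel_weight must be >= 1")
        if not self.defects_present and self.defect_width not in (None, 0, 0.0):
            if self.defect_width is not None and self.defect_width > 0:
                raise ValueError("defect_width set while defects_present is False")
        if self.defects_present and self.resolved_defect_width() <= 0:
            raise ValueError("defect_width must be > 0 when defects_present")
        if not 0 <= self.strut_reactivity <= 1:
            raise ValueError("strut_reactivity must lie in [0, 1]")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if self.flow_model not in ("quasi_steady", "unsteady"):
            raise ValueError("flow_model must be 'quasi_steady' or 'unsteady'")
        if self.inflow_shape not in ("poiseuille", "plug"):
            raise ValueError("inflow_shape must be 'poiseuille' or 'plug'")
        if self.n_struts >= 2 and self.strut_spacing < self.strut_diameter:
            raise InvalidGeometryError(
                f"strut_spacing {self.strut_spacing} < strut diameter "
                f"{self.strut_diameter}: struts overlap")

    # -- derived quantities -------------------------------------------
    def resolved_defect_width(self) -> float:
        return self.strut_diameter if self.defect_width is None else self.defect_width

    def resolved_defect_depth(self) -> float:
        return 0.5 * self.strut_diameter if self.defect_depth is None else self.defect_depth

    @property
    def kinematic_viscosity_mm2(self) -> float:
        """nu in mm^2/s (1.004e-6 m^2/s == 1.004 mm^2/s)."""
        return self.dynamic_viscosity / self.blood_density * 1.0e6

    @property
    def platelet_density_mm3(self) -> float:
        """Number density per mm^3 (1 ml == 1000 mm^3)."""
        return self.platelet_density / 1000.0

    @property
    def thickness(self) -> float:
        """Represented transverse extent (mm): slab in 2-D, width in 3-D."""
        return self.slab_thickness if self.mode == "2d" else self.domain_width

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # -- flat key-value scenario file ---------------------------------
    def to_yaml(self, path=None) -> str:
        header = (
            "# stentflow scenario file.  Units: lengths mm (except *_um fields,\n"
            "# micrometres), times s, speeds mm/s, blood_density kg/m^3,\n"
            "# dynamic_viscosity Pa.s, platelet_density 1/ml, spring_constant N/m,\n"
            "# damping N.s/m, rupture_force N, rates 1/s.\n")
        body = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        text = header + body
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "snapshot_times" in data:
            data["snapshot_times"] = tuple(data["snapshot_times"])
        return cls(**data)


# ======================================================================
# Geometry
# ======================================================================

@dataclass
class Geometry:
    """Wall, strut array and optional defect cavities.

    The wall occupies ``z < 0`` except where a defect cavity has carved the
    tissue away; each strut is a cylinder of radius ``strut_radius`` with its
    axis along x at height z = 0 (so exactly half is embedded).  A defect
    cavity is a groove around a strut: ``-defect_depth <= z < 0`` within
    horizontal distance ``strut_radius + defect_width`` of the strut axis.
    """

    strut_radius: float
    strut_y: np.ndarray                 # streamwise centers, mm
    defects_present: bool
    defect_width: float
    defect_depth: float
    reactivity: dict = field(default_factory=dict)  # patch label -> factor
    # injured (stent-denuded) wall segment; wall outside it is healthy
    # endothelium and non-reactive.  None -> the whole wall is injured.
    injured_span: tuple | None = None

    @property
    def n_struts(self) -> int:
        return len(self.strut_y)

    @property
    def cavity_halfwidth(self) -> float:
        return self.strut_radius + self.defect_width

    @property
    def z_floor(self) -> float:
        """Lowest fluid z (cavity floor if defects, else wall surface)."""
        return -self.defect_depth if self.defects_present else 0.0

    # ------------------------------------------------------------------
    def in_strut(self, y, z):
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        if self.n_struts == 0:
            return np.zeros(np.broadcast(y, z).shape, dtype=bool)
        dy = y[..., None] - self.strut_y
        r2 = dy * dy + (z * z)[..., None]
        return np.any(r2 <= self.strut_radius ** 2, axis=-1)

    def in_cavity(self, y, z):
        """Inside a defect cavity (fluid region carved out of the wall)."""
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        if not self.defects_present or self.n_struts == 0:
            return np.zeros(np.broadcast(y, z).shape, dtype=bool)
        dy = np.abs(y[..., None] - self.strut_y)
        box = np.any(dy <= self.cavity_halfwidth, axis=-1)
        depth_ok = (z < 0) & (z >= -self.defect_depth)
        return box & depth_ok & ~self.in_strut(y, z)

    def is_solid(self, y, z):
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        wall = (z < 0) & ~self.in_cavity(y, z)
        return wall | self.in_strut(y, z)

    def local_wall_height(self, y):
        """Top of the solid surface under streamwise station y (mm)."""
        y = np.asarray(y, dtype=float)
        h = np.zeros_like(y)
        if self.defects_present and self.n_struts:
            dy = np.abs(y[..., None] - self.strut_y)
            in_mouth = np.any(dy <= self.cavity_halfwidth, axis=-1)
            h = np.where(in_mouth, -self.defect_depth, h)
        if self.n_struts:
            dy = np.abs(y[..., None] - self.strut_y)
            under = dy <= self.strut_radius
            cap = np.sqrt(np.maximum(self.strut_radius ** 2 - dy ** 2, 0.0))
            h = np.maximum(h, np.max(np.where(under, cap, -np.inf), axis=-1))
        return h

    # ------------------------------------------------------------------
    def nearest_surface(self, y, z):
        """Nearest reactive surface point for fluid-side query points.

        Returns ``(dist, anchor_y, anchor_z, label)`` where ``dist`` is the
        center-to-surface distance (mm) and ``label`` a PATCH_* code.
        Surfaces are x-invariant, so the transverse coordinate passes through
        unchanged by the caller.
        """
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        shape = np.broadcast(y, z).shape
        y = np.broadcast_to(y, shape).astype(float)
        z = np.broadcast_to(z, shape).astype(float)

        best_d = np.full(shape, np.inf)
        best_ay = np.zeros(shape)
        best_az = np.zeros(shape)
        best_lab = np.full(shape, PATCH_WALL, dtype=np.int8)

        def consider(d, ay, az, lab):
            nonlocal best_d, best_ay, best_az, best_lab
            better = d < best_d
            best_d = np.where(better, d, best_d)
            best_ay = np.where(better, ay, best_ay)
            best_az = np.where(better, az, best_az)
            best_lab = np.where(better, lab, best_lab)

        # Exposed wall plane z=0: excluded under strut footprints and, with
        # defects, under the full cavity mouth; clamp y to the nearest edge.
        excl = self.cavity_halfwidth if self.defects_present else self.strut_radius
        ay = y.copy()
        if self.n_struts:
            for yc in self.strut_y:
                dy = ay - yc
                inside = np.abs(dy) < excl
                ay = np.where(inside, yc + np.sign(np.where(dy == 0, 1.0, dy)) * excl, ay)
        d = np.hypot(y - ay, z)
        if self.injured_span is None:
            wall_lab = np.full(shape, PATCH_WALL, dtype=np.int8)
        else:
            inj = (ay >= self.injured_span[0]) & (ay <= self.injured_span[1])
            wall_lab = np.where(inj, PATCH_WALL, PATCH_HEALTHY).astype(np.int8)
        consider(d, ay, np.zeros(shape), wall_lab)

        # Strut surfaces.
        for yc in self.strut_y:
            dy = y - yc
            rr = np.hypot(dy, z)
            safe = np.maximum(rr, 1e-12)
            ayc = yc + dy / safe * self.strut_radius
            azc = z / safe * self.strut_radius
            if not self.defects_present:
                # only the z >= 0 half is exposed
                below = azc < 0
                ayc = np.where(below, yc + np.sign(np.where(dy == 0, 1.0, dy)) * self.strut_radius, ayc)
                azc = np.where(below, 0.0, azc)
            d = np.hypot(y - ayc, z - azc)
            consider(d, ayc, azc, PATCH_STRUT)

        # Cavity floor and side walls.
        if self.defects_present:
            B, D = self.cavity_halfwidth, self.defect_depth
            for yc in self.strut_y:
                ayf = np.clip(y, yc - B, yc + B)
                d = np.hypot(y - ayf, z + D)
                consider(d, ayf, np.full(shape, -D), PATCH_DEFECT)
                for side in (-1.0, 1.0):
                    ys = yc + side * B
                    azs = np.clip(z, -D, 0.0)
                    d = np.hypot(y - ys, z - azs)
                    consider(d, np.full(shape, ys), azs, PATCH_DEFECT)

        return best_d, best_ay, best_az, best_lab

    def fluid_volume(self, domain_length: float, domain_height: float,
                     thickness: float) -> float:
        """Analytic fluid volume (mm^3) of the channel patch."""
        area = domain_length * domain_height
        R = self.strut_radius
        area -= self.n_struts * 0.5 * np.pi * R ** 2  # exposed strut caps
        if self.defects_present:
            D = self.defect_depth
            per_cavity = 2 * self.cavity_halfwidth * D
            if D >= R:
                buried_overlap = 0.5 * np.pi * R ** 2
            else:
                # strut area within the cavity depth band z in [-D, 0]:
                # half disc minus the circular segment below z = -D
                segment = R * R * np.arccos(D / R) - D * np.sqrt(R * R - D * D)
                buried_overlap = 0.5 * np.pi * R ** 2 - segment
            area += self.n_struts * (per_cavity - buried_overlap)
        return area * thickness


def build_geometry(cfg: SimulationConfig) -> Geometry:
    """Construct the strut/defect geometry described by ``cfg``.

    Raises :class:`InvalidGeometryError` when struts overlap or fall outside
    the domain.
    """
    cfg.validate()
    ys = cfg.first_strut_y + cfg.strut_spacing * np.arange(cfg.n_struts)
    if cfg.n_struts >= 2 and cfg.strut_spacing < cfg.strut_diameter:
        raise InvalidGeometryError("struts overlap")
    if cfg.n_struts and (ys.min() - cfg.strut_diameter < 0
                         or ys.max() + cfg.strut_diameter > cfg.domain_length):
        raise InvalidGeometryError("strut outside domain footprint")
    d = cfg.strut_diameter
    if cfg.n_struts:
        injured = (float(ys.min() - 0.5 * d - cfg.region_upstream_diameters * d),
                   float(ys.max() + 0.5 * d + cfg.region_downstream_diameters * d))
    else:
        injured = None
    return Geometry(
        strut_radius=0.5 * cfg.strut_diameter,
        strut_y=ys,
        defects_present=bool(cfg.defects_present and cfg.n_struts),
        defect_width=cfg.resolved_defect_width(),
        defect_depth=cfg.resolved_defect_depth(),
        reactivity={PATCH_WALL: cfg.wall_reactivity,
                    PATCH_DEFECT: cfg.defect_reactivity,
                    PATCH_STRUT: cfg.strut_reactivity,
                    PATCH_HEALTHY: 0.0},
        injured_span=injured,
    )


# ======================================================================
# Grid
# ======================================================================

@dataclass
class Grid:
    """Uniform staggered Cartesian grid.  Origin at the lower corner."""

    nx: int
    ny: int
    nz: int
    h: float            # isotropic spacing, mm
    x0: float
    y0: float
    z0: float

    @property
    def shape(self):
        return (self.nx, self.ny, self.nz)

    @property
    def y_max(self):
        return self.y0 + self.ny * self.h

    @property
    def z_max(self):
        return self.z0 + self.nz * self.h

    @property
    def yc(self):
        return self.y0 + (np.arange(self.ny) + 0.5) * self.h

    @property
    def zc(self):
        return self.z0 + (np.arange(self.nz) + 0.5) * self.h

    @property
    def xc(self):
        return self.x0 + (np.arange(self.nx) + 0.5) * self.h

    @property
    def zf(self):
        """z-face coordinates (length nz + 1)."""
        return self.z0 + np.arange(self.nz + 1) * self.h

    @property
    def yf(self):
        return self.y0 + np.arange(self.ny + 1) * self.h


def build_grid(cfg: SimulationConfig, geometry: Geometry) -> Grid:
    """Discretize the domain; spacing must resolve any strut (h <= d/6)."""
    h = cfg.grid_spacing
    if geometry.n_struts and h > cfg.strut_diameter / 6 * (1 + 1e-9):
        raise ValueError(
            f"grid_spacing {h} too coarse: need <= strut_diameter/6 "
            f"= {cfg.strut_diameter / 6:.5f} mm to resolve the strut")
    if geometry.n_struts:
        clearance = cfg.domain_length - (geometry.strut_y.max()
                                         + 5 * cfg.strut_diameter)
        if clearance < 0:
            raise InvalidGeometryError(
                "domain must extend >= 5 strut diameters downstream of the "
                "last strut")
    # buried rows below z=0 so that struts and cavities are representable
    depth_needed = max(geometry.strut_radius,
                       geometry.defect_depth if geometry.defects_present else 0.0)
    n_below = int(np.ceil(depth_needed / h)) + 1 if geometry.n_struts else 0
    nz = int(round(cfg.domain_height / h)) + n_below
    ny = int(round(cfg.domain_length / h))
    nx = int(round(cfg.domain_width / h)) if cfg.mode == "3d" else 1
    return Grid(nx=nx, ny=ny, nz=nz, h=h, x0=0.0, y0=0.0, z0=-n_below * h)


def solid_mask(geometry: Geometry, grid: Grid) -> np.ndarray:
    """Cell-center solid mask, shape (nx, ny, nz); True where solid."""
    Y, Z = np.meshgrid(grid.yc, grid.zc, indexing="ij")
    mask2d = geometry.is_solid(Y, Z)
    return np.broadcast_to(mask2d[None, :, :], grid.shape).copy()


# ======================================================================
# Inflow and seeding
# ======================================================================

def inflow_profile(t, cfg: SimulationConfig):
    """Sawtooth inflow speed (mm/s): linear ramp 0 -> peak each period."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    phase = np.mod(t, cfg.waveform_period) / cfg.waveform_period
    return cfg.peak_inflow * phase


def inlet_shape(z, cfg: SimulationConfig):
    """Normalized streamwise profile over wall-normal position z.

    ``poiseuille`` is the developed half-channel profile (no-slip at z=0,
    symmetry at z=H) normalized to unit *mean*; ``plug`` is 1 in the fluid.
    Zero for z <= 0 (buried rows).
    """
    z = np.asarray(z, dtype=float)
    H = cfg.domain_height
    zeta = np.clip(z / H, 0.0, 1.0)
    if cfg.inflow_shape == "plug":
        prof = np.ones_like(zeta)
    else:
        prof = 1.5 * (2 * zeta - zeta ** 2)
    return np.where(z > 0, prof, 0.0)


def seed_platelets(cfg: SimulationConfig, geometry: Geometry,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniformly seed parcel positions in the fluid; returns (N, 3) mm.

    The expected count is ``platelet_density x fluid volume / parcel_weight``
    and the realized count a Poisson draw.  Rejection sampling guarantees no
    position lies inside a strut or the wall.
    """
    vol = geometry.fluid_volume(cfg.domain_length, cfg.domain_height,
                                cfg.thickness)
    if vol <= 0:
        return np.zeros((0, 3))
    lam = cfg.platelet_density_mm3 * vol / cfg.parcel_weight
    n = int(rng.poisson(lam))
    z_lo = geometry.z_floor
    a = cfg.platelet_radius_um * 1e-3
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 1.3) + 16, 16)
        x = rng.uniform(0.0, cfg.thickness, m)
        y = rng.uniform(0.0, cfg.domain_length, m)
        z = rng.uniform(z_lo, cfg.domain_height, m)
        ok = ~geometry.is_solid(y, z)
        # excluded volume: a platelet center sits at least one radius off
        # any surface
        if np.any(ok):
            dist, _, _, _ = geometry.nearest_surface(y[ok], z[ok])
            sub = np.flatnonzero(ok)
            ok[sub[dist < a]] = False
        k = min(int(ok.sum()), n - filled)
        idx = np.flatnonzero(ok)[:k]
        out[filled:filled + k, 0] = x[idx]
        out[filled:filled + k, 1] = y[idx]
        out[filled:filled + k, 2] = z[idx]
        filled += k
    return out
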