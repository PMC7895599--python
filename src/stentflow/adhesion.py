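"""Virtual-platelet adhesion model.

Each platelet is a point parcel with a nominal radius (1 um) used for drag
and gap computation.  The state machine is

    FREE --(attempt_tether)--> TETHERED --(activate)--> ADHERED
    TETHERED/ADHERED --(rupture_check)--> FREE

Tethering is distance-gated and stochastic: within a capture gap of a
reactive surface a bond forms with probability 1 - exp(-k_on * r * dt),
where r is the patch reactivity.  The bond is a Kelvin--Voigt element
(spring k and damper c in parallel, F = k x + c dx/dt, tensile positive)
representing GPIb-alpha/VWF capture; activation, triggered on adhesion,
multiplies the spring constant by alpha and divides the unstressed off-rate
by alpha, switching the same bond to firm GPIIb/IIIa-like parameters.
Rupture follows the Bell form k_off(F) = k_off0 * exp(F / F_c).

Tethered platelets move in quasi-static balance between Stokes drag
6 pi mu a (u_fluid - u_platelet) and the bond force: the radial extension
follows a linear overdamped relaxation (integrated exactly over the step)
while the platelet swings tangentially with the local flow at fixed bond
length.

Positions are mm and velocities mm/s; bond mechanics are evaluated in SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scenario import Geometry, SimulationConfig, PATCH_WALL
from .hemodynamics import FlowField, interp_velocity

FREE, TETHERED, ADHERED = 0, 1, 2
STATE_NAMES = {FREE: "FREE", TETHERED: "TETHERED", ADHERED: "ADHERED"}

MM = 1.0e-3   # m per mm
UM = 1.0e-3   # mm per um


def drag_coefficient(cfg: SimulationConfig) -> float:
    """Stokes drag 6 pi mu a in N s/m."""
    return 6.0 * np.pi * cfg.dynamic_viscosity * cfg.platelet_radius_um * 1e-6


KB = 1.380649e-23  # J/K


def brownian_diffusivity(cfg: SimulationConfig) -> float:
    """Stokes-Einstein translational diffusivity in mm^2/s."""
    return KB * cfg.temperature_K / drag_coefficient(cfg) * 1e6


def diffuse_free(arr: PlateletArrays, cfg: SimulationConfig, dt: float,
                 rng: np.random.Generator) -> None:
    """Thermal random walk of FREE platelets.

    Brownian motion is the only cross-streamline transport of free platelets
    in this model (red-cell-enhanced dispersion is out of scope); without it
    the sub-micrometre capture layer at the wall would deplete and never be
    replenished in steady parallel flow.
    """
    if not cfg.brownian_motion:
        return
    m = np.flatnonzero(arr.state == FREE)
    if m.size == 0:
        return
    sigma = np.sqrt(2.0 * brownian_diffusivity(cfg) * dt)
    kick = rng.standard_normal((m.size, 3)) * sigma
    if cfg.mode == "2d":
        kick[:, 0] = 0.0
    arr.pos[m] += kick


# ======================================================================
# Structure-of-arrays platelet population
# ======================================================================

class PlateletArrays:
    """Vectorized platelet population used by the engine.

    Backed by capacity-managed storage so per-step removal (swap-remove from
    the tail) and inlet injection are O(changed) rather than O(population).
    Field accessors return views of the live prefix; writing through fancy
    indexing mutates storage as expected.
    """

    _FIELDS = ("pos", "vel", "state", "active", "id", "anchor", "bond_k",
               "bond_c", "bond_koff0", "bond_rest", "bond_t0", "bond_patch")

    def __init__(self, n: int = 0):
        cap = max(n, 8)
        self._n = n
        self._pos = np.zeros((cap, 3))
        self._vel = np.zeros((cap, 3))
        self._state = np.zeros(cap, dtype=np.int8)
        self._active = np.zeros(cap, dtype=bool)
        self._id = np.zeros(cap, dtype=np.int64)
        self._anchor = np.zeros((cap, 3))
        self._bond_k = np.zeros(cap)
        self._bond_c = np.zeros(cap)
        self._bond_koff0 = np.zeros(cap)
        self._bond_rest = np.zeros(cap)   # mm
        self._bond_t0 = np.zeros(cap)
        self._bond_patch = np.full(cap, -1, dtype=np.int8)

    def __len__(self) -> int:
        return self._n

    # live views -------------------------------------------------------
    pos = property(lambda s: s._pos[:s._n])
    vel = property(lambda s: s._vel[:s._n])
    state = property(lambda s: s._state[:s._n])
    active = property(lambda s: s._active[:s._n])
    id = property(lambda s: s._id[:s._n])
    anchor = property(lambda s: s._anchor[:s._n])
    bond_k = property(lambda s: s._bond_k[:s._n])
    bond_c = property(lambda s: s._bond_c[:s._n])
    bond_koff0 = property(lambda s: s._bond_koff0[:s._n])
    bond_rest = property(lambda s: s._bond_rest[:s._n])
    bond_t0 = property(lambda s: s._bond_t0[:s._n])
    bond_patch = property(lambda s: s._bond_patch[:s._n])

    def _grow(self, need: int) -> None:
        cap = self._pos.shape[0]
        if need <= cap:
            return
        new_cap = max(need, int(cap * 1.6) + 8)
        for f in self._FIELDS:
            old = getattr(self, "_" + f)
            shape = (new_cap,) + old.shape[1:]
            new = np.zeros(shape, dtype=old.dtype)
            if f == "bond_patch":
                new[:] = -1
            new[:cap] = old
            setattr(self, "_" + f, new)

    def extend(self, other: "PlateletArrays") -> "PlateletArrays":
        m = len(other)
        self._grow(self._n + m)
        a, b = self._n, self._n + m
        for f in self._FIELDS:
            getattr(self, "_" + f)[a:b] = getattr(other, f)
        self._n = b
        return self

    def remove(self, idx: np.ndarray) -> None:
        """Swap-remove the given (unique) indices."""
        g = np.unique(np.asarray(idx, dtype=np.int64))
        if g.size == 0:
            return
        n_new = self._n - g.size
        tail = np.arange(n_new, self._n)
        tail_alive = tail[~np.isin(tail, g)]
        holes = g[g < n_new]
        for f in self._FIELDS:
            arr = getattr(self, "_" + f)
            arr[holes] = arr[tail_alive]
        self._n = n_new

    def compress(self, keep: np.ndarray) -> "PlateletArrays":
        """New compacted population of the rows where ``keep`` is True."""
        out = PlateletArrays(int(np.count_nonzero(keep)))
        for f in self._FIELDS:
            getattr(out, "_" + f)[:len(out)] = getattr(self, f)[keep]
        return out

    def copy(self) -> "PlateletArrays":
        return self.compress(np.ones(len(self), dtype=bool))

    @property
    def n_bonded(self) -> int:
        return int(np.count_nonzero(self.state != FREE))

    def clear_bond(self, idx) -> None:
        self.state[idx] = FREE
        self.anchor[idx] = 0.0
        self.bond_k[idx] = 0.0
        self.bond_c[idx] = 0.0
        self.bond_koff0[idx] = 0.0
        self.bond_rest[idx] = 0.0
        self.bond_t0[idx] = 0.0
        self.bond_patch[idx] = -1


# ======================================================================
# Vectorized kernels
# ======================================================================

def advect_free(arr: PlateletArrays, flow: FlowField, dt: float) -> None:
    """RK2 (midpoint) transport of FREE platelets by the interpolated flow."""
    from .hemodynamics import _HAVE_NUMBA, _advect_rk2_2d
    g = flow.grid
    if g.nx == 1 and _HAVE_NUMBA:
        idx = np.flatnonzero(arr.state == FREE)
        if idx.size:
            _advect_rk2_2d(flow.v[0], flow.w[0], arr.pos, arr.vel, idx, dt,
                           g.y0, g.z0, g.h, g.ny, g.nz)
        return
    m = arr.state == FREE
    if not np.any(m):
        return
    p0 = arr.pos[m]
    u1 = interp_velocity(flow, p0)
    mid = p0 + 0.5 * dt * u1
    u2 = interp_velocity(flow, mid)
    arr.pos[m] = p0 + dt * u2
    arr.vel[m] = u2


def surface_outward_normal(geometry: Geometry, pos, anchor, label):
    """Unit outward (into-fluid) normal at surface anchor points."""
    d = pos - anchor
    nrm = np.linalg.norm(d, axis=1)
    n = np.where(nrm[:, None] > 1e-12, d / np.maximum(nrm, 1e-12)[:, None], 0.0)
    # fall back to analytic normals for degenerate/penetrating points
    bad = nrm <= 1e-12
    fluid_side = ~geometry.is_solid(pos[:, 1], pos[:, 2])
    bad |= ~fluid_side
    if np.any(bad):
        nb = np.zeros((int(bad.sum()), 3))
        ab = anchor[bad]
        lb = label[bad]
        # strut: radial from nearest axis; wall/cavity floor: +z; side: +-y
        if geometry.n_struts:
            dy = ab[:, 1][:, None] - geometry.strut_y
            nearest = np.argmin(np.abs(dy), axis=1)
            dyn = dy[np.arange(len(ab)), nearest]
            rr = np.hypot(dyn, ab[:, 2])
            strut_n = np.stack([np.zeros_like(dyn),
                                np.where(rr > 1e-12, dyn / np.maximum(rr, 1e-12), 0.0),
                                np.where(rr > 1e-12, ab[:, 2] / np.maximum(rr, 1e-12), 1.0)],
                               axis=1)
        else:
            strut_n = np.zeros((len(ab), 3))
        up = np.zeros((len(ab), 3))
        up[:, 2] = 1.0
        from .scenario import PATCH_STRUT, PATCH_DEFECT
        nb = np.where((lb == PATCH_STRUT)[:, None], strut_n, up)
        if geometry.defects_present and geometry.n_struts:
            side = (lb == PATCH_DEFECT) & (ab[:, 2] < -1e-12) & (ab[:, 2] > -geometry.defect_depth + 1e-12)
            if np.any(side):
                dy = ab[side, 1][:, None] - geometry.strut_y
                nearest = np.argmin(np.abs(dy), axis=1)
                sgn = np.sign(dy[np.arange(int(side.sum())), nearest])
                sv = np.zeros((int(side.sum()), 3))
                sv[:, 1] = sgn
                nb[side] = sv
        n[bad] = nb
    return n


def resolve_contacts(arr: PlateletArrays, geometry: Geometry,
                     cfg: SimulationConfig) -> None:
    """Project penetrating/overlapping platelet centers back to contact.

    A platelet center may come no closer than one radius to any surface;
    centers inside solid are pushed out along the outward normal.
    """
    if len(arr) == 0:
        return
    a = cfg.platelet_radius_um * UM
    y, z = arr.pos[:, 1], arr.pos[:, 2]
    # quick prefilter: anything near or below the surface envelope
    top = geometry.strut_radius if geometry.n_struts else 0.0
    near = z < top + 2 * a
    if not np.any(near):
        return
    dist, ay, az, lab = geometry.nearest_surface(y[near], z[near])
    inside = geometry.is_solid(y[near], z[near])
    too_close = (dist < a) | inside
    if not np.any(too_close):
        return
    sel = np.flatnonzero(near)[too_close]
    anchor = np.stack([arr.pos[sel, 0], ay[too_close], az[too_close]], axis=1)
    n = surface_outward_normal(geometry, arr.pos[sel], anchor, lab[too_close])
    arr.pos[sel] = anchor + a * n


def attempt_tether_arrays(arr: PlateletArrays, geometry: Geometry,
                          cfg: SimulationConfig, t: float, dt: float,
                          rng: np.random.Generator,
                          occupancy: Optional[dict] = None,
                          rate_factor: float = 1.0) -> np.ndarray:
    """Stochastic tether formation for FREE platelets near reactive surfaces.

    ``rate_factor`` carries the shear gating (instantaneous driving flow over
    its peak) applied uniformly to every patch.  Returns the indices of
    platelets that tethered this step.
    """
    a = cfg.platelet_radius_um * UM
    dcap = cfg.capture_distance_um * UM
    top = geometry.strut_radius if geometry.n_struts else 0.0
    cand = np.flatnonzero((arr.state == FREE)
                          & (arr.pos[:, 2] < top + 4 * (a + dcap)))
    if cand.size == 0:
        return cand
    y, z = arr.pos[cand, 1], arr.pos[cand, 2]
    dist, ay, az, lab = geometry.nearest_surface(y, z)
    gap = dist - a
    lut = np.zeros(8)
    for code, r in geometry.reactivity.items():
        lut[code] = r
    react = lut[lab]
    rate = cfg.k_on * cfg.kon_scale * rate_factor * react
    p = np.where(gap <= dcap, 1.0 - np.exp(-rate * dt), 0.0)
    hit = rng.random(cand.size) < p
    sel = cand[hit]
    if sel.size and occupancy is not None:
        sel = _enforce_packing(arr, ay[hit], cfg, sel, occupancy)
        hit = np.isin(cand, sel)
    if sel.size == 0:
        return sel
    arr.state[sel] = TETHERED
    arr.anchor[sel, 0] = arr.pos[sel, 0]
    arr.anchor[sel, 1] = ay[hit]
    arr.anchor[sel, 2] = az[hit]
    arr.bond_k[sel] = cfg.spring_constant
    arr.bond_c[sel] = cfg.damping
    arr.bond_koff0[sel] = cfg.k_off0
    arr.bond_rest[sel] = cfg.bond_rest_length_um * UM
    arr.bond_t0[sel] = t
    arr.bond_patch[sel] = lab[hit]
    return sel


def _enforce_packing(arr, anchor_y, cfg, sel, occupancy):
    """Monolayer packing cap: at most one adhered platelet per
    ``monolayer_packing_um2`` of wall footprint, bookkept in 2 um bins."""
    bin_mm = 0.002
    cap = max(int(bin_mm * cfg.thickness * 1e6 / cfg.monolayer_packing_um2), 1)
    keep = np.ones(sel.size, dtype=bool)
    for i, ybin in enumerate((anchor_y / bin_mm).astype(np.int64)):
        cnt = occupancy.get(int(ybin), 0)
        if cnt >= cap:
            keep[i] = False
        else:
            occupancy[int(ybin)] = cnt + 1
    return sel[keep]


def release_packing(arr, idx, cfg, occupancy):
    bin_mm = 0.002
    for ybin in (arr.anchor[idx, 1] / bin_mm).astype(np.int64):
        key = int(ybin)
        if occupancy.get(key, 0) > 0:
            occupancy[key] -= 1


def update_tethered_arrays(arr: PlateletArrays, flow: FlowField,
                           cfg: SimulationConfig, dt: float) -> np.ndarray:
    """Quasi-static drag/bond force balance for bonded platelets.

    Returns per-platelet tensile bond force (N), zero for unbonded.
    """
    forces = np.zeros(len(arr))
    m = np.flatnonzero(arr.state != FREE)
    if m.size == 0:
        return forces
    gamma = drag_coefficient(cfg)
    pos = arr.pos[m]
    anchor = arr.anchor[m]
    r = pos - anchor
    dist = np.linalg.norm(r, axis=1)
    rhat = np.where(dist[:, None] > 1e-12, r / np.maximum(dist, 1e-12)[:, None],
                    np.array([0.0, 0.0, 1.0]))
    uf = interp_velocity(flow, pos) * MM          # m/s
    u_r = np.einsum("ij,ij->i", uf, rhat)
    k = arr.bond_k[m]
    c = arr.bond_c[m]
    L0 = arr.bond_rest[m] * MM                    # m
    x_old = np.maximum(dist * MM - L0, 0.0)
    tau = (gamma + c) / k
    x_inf = np.maximum(gamma * u_r / k, 0.0)
    decay = np.exp(-dt / tau)
    x_new = x_inf + (x_old - x_inf) * decay
    xdot = (x_new - x_old) / dt
    forces[m] = np.maximum(k * x_new + c * xdot, 0.0)
    # tangential swing at fixed length, then renormalize
    u_t = uf - u_r[:, None] * rhat
    new_r = rhat * ((L0 + x_new) / MM)[:, None] + u_t * dt / MM
    nrm = np.linalg.norm(new_r, axis=1)
    new_r = new_r / np.maximum(nrm, 1e-15)[:, None] * ((L0 + x_new) / MM)[:, None]
    new_pos = anchor + new_r
    arr.vel[m] = (new_pos - pos) / dt
    arr.pos[m] = new_pos
    return forces


def activate_arrays(arr: PlateletArrays, cfg: SimulationConfig,
                    t: float) -> np.ndarray:
    """Activation on adhesion: firm-bond switch for due TETHERED platelets."""
    m = np.flatnonzero((arr.state == TETHERED)
                       & (t - arr.bond_t0 >= cfg.activation_delay - 1e-12))
    if m.size:
        alpha = cfg.activation_multiplier
        arr.bond_k[m] *= alpha
        arr.bond_koff0[m] /= alpha
        arr.active[m] = True
        arr.state[m] = ADHERED
    return m


def rupture_check_arrays(arr: PlateletArrays, cfg: SimulationConfig,
                         dt: float, rng: np.random.Generator,
                         forces: np.ndarray,
                         occupancy: Optional[dict] = None):
    """Bell-model stochastic rupture.

    Returns ``(broke, patches)``: indices that detached this step and the
    patch labels their bonds were anchored on (for event logging).
    """
    m = np.flatnonzero(arr.state != FREE)
    if m.size == 0:
        return m, np.zeros(0, dtype=np.int8)
    koff = arr.bond_koff0[m] * np.exp(np.minimum(forces[m] / cfg.rupture_force, 60.0))
    p = 1.0 - np.exp(-koff * dt)
    broke = m[rng.random(m.size) < p]
    patches = arr.bond_patch[broke].copy()
    if broke.size:
        if occupancy is not None:
            release_packing(arr, broke, cfg, occupancy)
        arr.clear_bond(broke)
    return broke, patches


# ======================================================================
# Single-platelet API
# ======================================================================

@dataclass
class Bond:
    """Kelvin--Voigt bond record anchored on a reactive surface patch."""

    anchor: np.ndarray                  # mm
    spring_constant: float              # N/m
    damping: float                      # N s/m
    rest_length_um: float
    formation_time: float
    patch: int = PATCH_WALL
    off_rate0: float = 0.0

    def __post_init__(self):
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be > 0")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")


@dataclass
class Platelet:
    """A single Lagrangian platelet (convenience view for the collection)."""

    id: int = 0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    state: int = FREE
    activated: bool = False
    bond: Optional[Bond] = None
    radius_um: float = 1.0

    def __post_init__(self):
        if (self.state == FREE) != (self.bond is None):
            raise ValueError("state FREE <=> no bond")
        if self.state == ADHERED and not self.activated:
            raise ValueError("ADHERED implies activated")


def _to_arrays(p: Platelet) -> PlateletArrays:
    arr = PlateletArrays(1)
    arr.pos[0] = p.position
    arr.vel[0] = p.velocity
    arr.state[0] = p.state
    arr.active[0] = p.activated
    arr.id[0] = p.id
    if p.bond is not None:
        arr.anchor[0] = p.bond.anchor
        arr.bond_k[0] = p.bond.spring_constant
        arr.bond_c[0] = p.bond.damping
        arr.bond_koff0[0] = p.bond.off_rate0
        arr.bond_rest[0] = p.bond.rest_length_um * UM
        arr.bond_t0[0] = p.bond.formation_time
        arr.bond_patch[0] = p.bond.patch
    return arr


def _from_arrays(arr: PlateletArrays, template: Platelet) -> Platelet:
    bond = None
    if arr.state[0] != FREE:
        bond = Bond(anchor=arr.anchor[0].copy(),
                    spring_constant=float(arr.bond_k[0]),
                    damping=float(arr.bond_c[0]),
                    rest_length_um=float(arr.bond_rest[0] / UM),
                    formation_time=float(arr.bond_t0[0]),
                    patch=int(arr.bond_patch[0]),
                    off_rate0=float(arr.bond_koff0[0]))
    return Platelet(id=int(arr.id[0]), position=arr.pos[0].copy(),
                    velocity=arr.vel[0].copy(), state=int(arr.state[0]),
                    activated=bool(arr.active[0]), bond=bond,
                    radius_um=template.radius_um)


def advect_platelet(p: Platelet, flow: FlowField, dt: float,
                    geometry: Geometry | None = None,
                    cfg: SimulationConfig | None = None) -> Platelet:
    """Transport a FREE platelet one step; resolves solid penetration when
    the geometry is supplied."""
    if p.state != FREE:
        raise ValueError("advect_platelet requires a FREE platelet")
    arr = _to_arrays(p)
    advect_free(arr, flow, dt)
    if geometry is not None:
        resolve_contacts(arr, geometry, cfg or SimulationConfig())
    return _from_arrays(arr, p)


def attempt_tether(p: Platelet, geometry: Geometry, dt: float,
                   rng: np.random.Generator,
                   cfg: SimulationConfig | None = None, t: float = 0.0) -> Platelet:
    if p.state != FREE:
        raise ValueError("attempt_tether requires a FREE platelet")
    cfg = cfg or SimulationConfig()
    arr = _to_arrays(p)
    attempt_tether_arrays(arr, geometry, cfg, t, dt, rng)
    return _from_arrays(arr, p)


def bond_force(b: Bond, extension_um: float, extension_rate_um_s: float) -> float:
    """Kelvin--Voigt force (N): F = k x + c dx/dt, tensile positive."""
    return (b.spring_constant * extension_um * 1e-6
            + b.damping * extension_rate_um_s * 1e-6)


def update_tethered(p: Platelet, flow: FlowField, dt: float,
                    cfg: SimulationConfig | None = None) -> Platelet:
    if p.state == FREE:
        raise ValueError("update_tethered requires a bonded platelet")
    arr = _to_arrays(p)
    update_tethered_arrays(arr, flow, cfg or SimulationConfig(), dt)
    return _from_arrays(arr, p)


def activate(p: Platelet, cfg: SimulationConfig | None = None,
             t: float = None) -> Platelet:
    """Firm-adhesion switch; no-op on FREE platelets, idempotent."""
    if p.state != TETHERED:
        return p
    cfg = cfg or SimulationConfig()
    arr = _to_arrays(p)
    activate_arrays(arr, cfg, t if t is not None
                    else float(arr.bond_t0[0] + cfg.activation_delay))
    return _from_arrays(arr, p)


def rupture_check(p: Platelet, dt: float, rng: np.random.Generator,
                  cfg: SimulationConfig | None = None,
                  force: float = 0.0) -> Platelet:
    if p.state == FREE:
        raise ValueError("rupture_check requires a bonded platelet")
    cfg = cfg or SimulationConfig()
    arr = _to_arrays(p)
    forces = np.array([force])
    rupture_check_arrays(arr, cfg, dt, rng, forces)
    return _from_arrays(arr, p)
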