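"""Incompressible Navier--Stokes on the masked Cartesian grid.

Chorin-style projection on a staggered (MAC) grid: explicit first-order
upwind advection, explicit centered diffusion, and an exact pressure
projection through a prefactorized sparse Poisson solve.  Solids are a
staircase binary mask; every velocity face touching a solid cell is held at
zero (first-order immersed boundary).  The regime of interest is viscous
laminar flow (channel Reynolds number of order 10-100, strut Reynolds number
of order 1), so no turbulence model is involved.

Boundary conditions: prescribed inflow at y = 0 (sawtooth waveform times a
plug or developed profile), convective (zero-gradient + projection) outflow
at y = L, no-slip at the bottom, free-slip rigid lid at the top, periodic in
the transverse x direction (trivially so in 2-D mode, nx = 1).

Internal units: mm, s; pressure is kinematic (divided by density).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

try:  # optional JIT for the particle-interpolation hot loop
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _interp2d_vw(v, w, ys, zs, y0, z0, h, ny, nz, out):
    """Bilinear staggered interpolation of (v, w) at 2-D points."""
    for i in range(ys.shape[0]):
        # v at (y_face, z_center)
        gy = (ys[i] - y0) / h
        j0 = int(np.floor(gy))
        if j0 < 0:
            j0 = 0
        elif j0 > ny - 1:
            j0 = ny - 1
        fy = gy - j0
        if fy < 0.0:
            fy = 0.0
        elif fy > 1.0:
            fy = 1.0
        gz = (zs[i] - z0) / h - 0.5
        k0 = int(np.floor(gz))
        if k0 < 0:
            k0 = 0
        elif k0 > nz - 2:
            k0 = nz - 2
        fz = gz - k0
        if fz < 0.0:
            fz = 0.0
        elif fz > 1.0:
            fz = 1.0
        out[i, 1] = ((1 - fy) * (1 - fz) * v[j0, k0]
                     + (1 - fy) * fz * v[j0, k0 + 1]
                     + fy * (1 - fz) * v[j0 + 1, k0]
                     + fy * fz * v[j0 + 1, k0 + 1])
        # w at (y_center, z_face)
        gy = (ys[i] - y0) / h - 0.5
        j0 = int(np.floor(gy))
        if j0 < 0:
            j0 = 0
        elif j0 > ny - 2:
            j0 = ny - 2
        fy = gy - j0
        if fy < 0.0:
            fy = 0.0
        elif fy > 1.0:
            fy = 1.0
        gz = (zs[i] - z0) / h
        k0 = int(np.floor(gz))
        if k0 < 0:
            k0 = 0
        elif k0 > nz - 1:
            k0 = nz - 1
        fz = gz - k0
        if fz < 0.0:
            fz = 0.0
        elif fz > 1.0:
            fz = 1.0
        out[i, 2] = ((1 - fy) * (1 - fz) * w[j0, k0]
                     + (1 - fy) * fz * w[j0, k0 + 1]
                     + fy * (1 - fz) * w[j0 + 1, k0]
                     + fy * fz * w[j0 + 1, k0 + 1])


@_njit(cache=True, inline="always")
def _interp2d_point(v, w, y, z, y0, z0, h, ny, nz):
    gy = (y - y0) / h
    j0 = int(np.floor(gy))
    j0 = 0 if j0 < 0 else (ny - 1 if j0 > ny - 1 else j0)
    fy = min(max(gy - j0, 0.0), 1.0)
    gz = (z - z0) / h - 0.5
    k0 = int(np.floor(gz))
    k0 = 0 if k0 < 0 else (nz - 2 if k0 > nz - 2 else k0)
    fz = min(max(gz - k0, 0.0), 1.0)
    vv = ((1 - fy) * (1 - fz) * v[j0, k0] + (1 - fy) * fz * v[j0, k0 + 1]
          + fy * (1 - fz) * v[j0 + 1, k0] + fy * fz * v[j0 + 1, k0 + 1])
    gy = (y - y0) / h - 0.5
    j0 = int(np.floor(gy))
    j0 = 0 if j0 < 0 else (ny - 2 if j0 > ny - 2 else j0)
    fy = min(max(gy - j0, 0.0), 1.0)
    gz = (z - z0) / h
    k0 = int(np.floor(gz))
    k0 = 0 if k0 < 0 else (nz - 1 if k0 > nz - 1 else k0)
    fz = min(max(gz - k0, 0.0), 1.0)
    ww = ((1 - fy) * (1 - fz) * w[j0, k0] + (1 - fy) * fz * w[j0, k0 + 1]
          + fy * (1 - fz) * w[j0 + 1, k0] + fy * fz * w[j0 + 1, k0 + 1])
    return vv, ww


@_njit(cache=True)
def _advect_rk2_2d(v, w, pos, vel, idx, dt, y0, z0, h, ny, nz):
    """In-place midpoint transport of the platelets listed in ``idx``."""
    for n in range(idx.shape[0]):
        i = idx[n]
        y, z = pos[i, 1], pos[i, 2]
        v1, w1 = _interp2d_point(v, w, y, z, y0, z0, h, ny, nz)
        ym, zm = y + 0.5 * dt * v1, z + 0.5 * dt * w1
        v2, w2 = _interp2d_point(v, w, ym, zm, y0, z0, h, ny, nz)
        pos[i, 1] = y + dt * v2
        pos[i, 2] = z + dt * w2
        vel[i, 0] = 0.0
        vel[i, 1] = v2
        vel[i, 2] = w2

from .scenario import Geometry, Grid, SimulationConfig, inflow_profile, inlet_shape, solid_mask


class SolverError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Staggered velocity + cell pressure with the associated solid mask.

    ``u``: x-faces (nx, ny, nz) (periodic, so nx faces);
    ``v``: y-faces (nx, ny+1, nz); ``w``: z-faces (nx, ny, nz+1);
    ``p``: cell centers (nx, ny, nz).
    """

    grid: Grid
    solid: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float = 0.0
    solver: Optional["ProjectionSolver"] = field(default=None, repr=False)

    @classmethod
    def zeros(cls, grid: Grid, solid: np.ndarray, t: float = 0.0) -> "FlowField":
        nx, ny, nz = grid.shape
        return cls(grid=grid, solid=solid,
                   u=np.zeros((nx, ny, nz)),
                   v=np.zeros((nx, ny + 1, nz)),
                   w=np.zeros((nx, ny, nz + 1)),
                   p=np.zeros((nx, ny, nz)), t=t)

    def copy(self) -> "FlowField":
        return FlowField(grid=self.grid, solid=self.solid,
                         u=self.u.copy(), v=self.v.copy(), w=self.w.copy(),
                         p=self.p.copy(), t=self.t, solver=self.solver)

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(self.u))) if self.u.size else 0.0,
                   float(np.max(np.abs(self.v))),
                   float(np.max(np.abs(self.w))))

    def divergence(self) -> np.ndarray:
        """Discrete divergence in every cell (1/s); zero in solid cells."""
        g = self.grid
        h = g.h
        div = ((self.v[:, 1:, :] - self.v[:, :-1, :]) / h
               + (self.w[:, :, 1:] - self.w[:, :, :-1]) / h)
        if g.nx > 1:
            div = div + (np.roll(self.u, -1, axis=0) - self.u) / h
        div[self.solid] = 0.0
        return div

    def inlet_flux(self) -> float:
        """Volumetric flux through the inlet per unit transverse cell (mm^2/s
        times h); comparable against :meth:`outlet_flux`."""
        return float(self.v[:, 0, :].sum()) * self.grid.h ** 2

    def outlet_flux(self) -> float:
        return float(self.v[:, -1, :].sum()) * self.grid.h ** 2


class ProjectionSolver:
    """Prefactorized projection solver bound to one grid + solid mask."""

    def __init__(self, grid: Grid, solid: np.ndarray, cfg: SimulationConfig):
        self.grid = grid
        self.solid = np.asarray(solid, dtype=bool)
        self.cfg = cfg
        self.nu = cfg.kinematic_viscosity_mm2  # mm^2/s
        nx, ny, nz = grid.shape
        fluid = ~self.solid

        # face zero-masks (faces adjacent to solid or closed boundaries)
        vz = np.zeros((nx, ny + 1, nz), dtype=bool)
        vz[:, 1:ny, :] = self.solid[:, :-1, :] | self.solid[:, 1:, :]
        vz[:, 0, :] = self.solid[:, 0, :]
        vz[:, ny, :] = self.solid[:, -1, :]
        self.v_zero = vz
        wz = np.zeros((nx, ny, nz + 1), dtype=bool)
        wz[:, :, 1:nz] = self.solid[:, :, :-1] | self.solid[:, :, 1:]
        wz[:, :, 0] = True
        wz[:, :, nz] = True
        self.w_zero = wz
        self.u_zero = self.solid | np.roll(self.solid, 1, axis=0)

        # correction masks (faces between two fluid cells; plus outlet)
        self.v_corr = np.zeros((nx, ny + 1, nz), dtype=bool)
        self.v_corr[:, 1:ny, :] = fluid[:, :-1, :] & fluid[:, 1:, :]
        self.outlet_fluid = fluid[:, -1, :]
        self.w_corr = np.zeros((nx, ny, nz + 1), dtype=bool)
        self.w_corr[:, :, 1:nz] = fluid[:, :, :-1] & fluid[:, :, 1:]
        self.u_corr = fluid & np.roll(fluid, 1, axis=0)

        self.fluid = fluid
        self.n_fluid = int(fluid.sum())
        self.idx = -np.ones(grid.shape, dtype=np.int64)
        self.idx[fluid] = np.arange(self.n_fluid)
        self._lu = splu(self._assemble_laplacian().tocsc())

        # inlet profile template over (nx, nz), unit mean speed
        prof = inlet_shape(grid.zc, cfg)          # (nz,)
        prof = np.broadcast_to(prof, (nx, nz)).copy()
        prof[self.solid[:, 0, :]] = 0.0
        self.inlet_template = prof

    def rebind(self, cfg: SimulationConfig) -> "ProjectionSolver":
        """Shallow copy bound to a new config, reusing the factorization
        (grid and solid mask must be unchanged)."""
        import copy
        out = copy.copy(self)
        out.cfg = cfg
        out.nu = cfg.kinematic_viscosity_mm2
        prof = inlet_shape(self.grid.zc, cfg)
        prof = np.broadcast_to(prof, (self.grid.nx, self.grid.nz)).copy()
        prof[self.solid[:, 0, :]] = 0.0
        out.inlet_template = prof
        return out

    # ------------------------------------------------------------------
    def _assemble_laplacian(self) -> sp.coo_matrix:
        g = self.grid
        nx, ny, nz = g.shape
        h2 = 1.0 / g.h ** 2
        idx = self.idx
        fluid = self.fluid
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_fluid)

        def add_pairs(cell_mask, ii, jj, kk):
            r = idx[cell_mask]
            c = idx[ii, jj, kk]
            rows.append(r)
            cols.append(c)
            vals.append(np.full(r.size, h2))
            np.add.at(diag, r, -h2)

        I, J, K = np.indices(g.shape)
        # y-
        m = fluid & (J > 0)
        m[m] &= fluid[I[m], J[m] - 1, K[m]]
        add_pairs(m, I[m], J[m] - 1, K[m])
        # y+
        m = fluid & (J < ny - 1)
        m[m] &= fluid[I[m], J[m] + 1, K[m]]
        add_pairs(m, I[m], J[m] + 1, K[m])
        # outlet open face (Dirichlet p=0 ghost)
        m = fluid & (J == ny - 1)
        np.add.at(diag, idx[m], -h2)
        # z-
        m = fluid & (K > 0)
        m[m] &= fluid[I[m], J[m], K[m] - 1]
        add_pairs(m, I[m], J[m], K[m] - 1)
        # z+
        m = fluid & (K < nz - 1)
        m[m] &= fluid[I[m], J[m], K[m] + 1]
        add_pairs(m, I[m], J[m], K[m] + 1)
        # x (periodic), only when nx > 1
        if nx > 1:
            for s in (-1, 1):
                m = fluid.copy()
                m[m] &= fluid[(I[m] + s) % nx, J[m], K[m]]
                add_pairs(m, (I[m] + s) % nx, J[m], K[m])

        rows.append(np.arange(self.n_fluid))
        cols.append(np.arange(self.n_fluid))
        vals.append(diag)
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_fluid, self.n_fluid))
        return A

    # ------------------------------------------------------------------
    def stable_dt(self, vmax: float) -> float:
        # harmonic combination of 90% of the FTCS diffusive bound
        # h^2/(2 nu ndim) and the advective CFL limit
        h, nu = self.grid.h, self.nu
        ndim = 3 if self.grid.nx > 1 else 2
        dt_diff = 0.45 * h * h / (nu * ndim)
        dt_adv = self.cfg.cfl * h / max(vmax, 1e-12)
        return 1.0 / (1.0 / dt_diff + 1.0 / dt_adv)

    def _apply_bcs(self, u, v, w, vin):
        v[:, 0, :] = vin
        v[:, -1, :] = v[:, -2, :]
        v[self.v_zero] = 0.0
        v[:, 0, :] = vin * (~self.solid[:, 0, :])
        w[self.w_zero] = 0.0
        if self.grid.nx > 1:
            u[self.u_zero] = 0.0
        else:
            u[:] = 0.0

    def _advect_diffuse(self, u, v, w, dt):
        g = self.grid
        h, nu = g.h, self.nu
        nx, ny, nz = g.shape
        vn, wn, un = v.copy(), w.copy(), u.copy()

        # ---- v momentum on interior y-faces (j = 1..ny-1) ----
        vc = v[:, 1:ny, :]
        vpz = np.concatenate([-v[:, :, :1], v, v[:, :, -1:]], axis=2)
        dvdy_b = (v[:, 1:ny, :] - v[:, 0:ny - 1, :]) / h
        dvdy_f = (v[:, 2:ny + 1, :] - v[:, 1:ny, :]) / h
        dvdz_b = (vpz[:, 1:ny, 1:-1] - vpz[:, 1:ny, :-2]) / h
        dvdz_f = (vpz[:, 1:ny, 2:] - vpz[:, 1:ny, 1:-1]) / h
        w_at_v = 0.25 * (w[:, 0:ny - 1, 0:nz] + w[:, 0:ny - 1, 1:nz + 1]
                         + w[:, 1:ny, 0:nz] + w[:, 1:ny, 1:nz + 1])
        adv = (np.where(vc > 0, dvdy_b, dvdy_f) * vc
               + np.where(w_at_v > 0, dvdz_b, dvdz_f) * w_at_v)
        lap = ((v[:, 2:ny + 1, :] - 2 * vc + v[:, 0:ny - 1, :]) / h ** 2
               + (vpz[:, 1:ny, 2:] - 2 * vc + vpz[:, 1:ny, :-2]) / h ** 2)
        if nx > 1:
            u_at_v = 0.25 * (u[:, 0:ny - 1, :] + u[:, 1:ny, :]
                             + np.roll(u, -1, axis=0)[:, 0:ny - 1, :]
                             + np.roll(u, -1, axis=0)[:, 1:ny, :])
            dvdx_b = (vc - np.roll(vc, 1, axis=0)) / h
            dvdx_f = (np.roll(vc, -1, axis=0) - vc) / h
            adv = adv + np.where(u_at_v > 0, dvdx_b, dvdx_f) * u_at_v
            lap = lap + (np.roll(vc, -1, axis=0) - 2 * vc
                         + np.roll(vc, 1, axis=0)) / h ** 2
        vn[:, 1:ny, :] = vc + dt * (nu * lap - adv)

        # ---- w momentum on interior z-faces (k = 1..nz-1) ----
        wc = w[:, :, 1:nz]
        wpy = np.concatenate([-w[:, :1, :], w, w[:, -1:, :]], axis=1)
        dwdz_b = (w[:, :, 1:nz] - w[:, :, 0:nz - 1]) / h
        dwdz_f = (w[:, :, 2:nz + 1] - w[:, :, 1:nz]) / h
        dwdy_b = (wpy[:, 1:-1, 1:nz] - wpy[:, :-2, 1:nz]) / h
        dwdy_f = (wpy[:, 2:, 1:nz] - wpy[:, 1:-1, 1:nz]) / h
        v_at_w = 0.25 * (v[:, 0:ny, 0:nz - 1] + v[:, 1:ny + 1, 0:nz - 1]
                         + v[:, 0:ny, 1:nz] + v[:, 1:ny + 1, 1:nz])
        adv = (np.where(wc > 0, dwdz_b, dwdz_f) * wc
               + np.where(v_at_w > 0, dwdy_b, dwdy_f) * v_at_w)
        lap = ((w[:, :, 2:nz + 1] - 2 * wc + w[:, :, 0:nz - 1]) / h ** 2
               + (wpy[:, 2:, 1:nz] - 2 * wc + wpy[:, :-2, 1:nz]) / h ** 2)
        if nx > 1:
            u_at_w = 0.25 * (u[:, :, 0:nz - 1] + u[:, :, 1:nz]
                             + np.roll(u, -1, axis=0)[:, :, 0:nz - 1]
                             + np.roll(u, -1, axis=0)[:, :, 1:nz])
            dwdx_b = (wc - np.roll(wc, 1, axis=0)) / h
            dwdx_f = (np.roll(wc, -1, axis=0) - wc) / h
            adv = adv + np.where(u_at_w > 0, dwdx_b, dwdx_f) * u_at_w
            lap = lap + (np.roll(wc, -1, axis=0) - 2 * wc
                         + np.roll(wc, 1, axis=0)) / h ** 2
        wn[:, :, 1:nz] = wc + dt * (nu * lap - adv)

        # ---- u momentum (3-D only; x-faces, periodic) ----
        if nx > 1:
            upy = np.concatenate([-u[:, :1, :], u, u[:, -1:, :]], axis=1)
            upz = np.concatenate([-u[:, :, :1], u, u[:, :, -1:]], axis=2)
            dudx_b = (u - np.roll(u, 1, axis=0)) / h
            dudx_f = (np.roll(u, -1, axis=0) - u) / h
            dudy_b = (upy[:, 1:-1, :] - upy[:, :-2, :]) / h
            dudy_f = (upy[:, 2:, :] - upy[:, 1:-1, :]) / h
            dudz_b = (upz[:, :, 1:-1] - upz[:, :, :-2]) / h
            dudz_f = (upz[:, :, 2:] - upz[:, :, 1:-1]) / h
            v_at_u = 0.25 * (v[:, 0:ny, :] + v[:, 1:ny + 1, :]
                             + np.roll(v, 1, axis=0)[:, 0:ny, :]
                             + np.roll(v, 1, axis=0)[:, 1:ny + 1, :])
            w_at_u = 0.25 * (w[:, :, 0:nz] + w[:, :, 1:nz + 1]
                             + np.roll(w, 1, axis=0)[:, :, 0:nz]
                             + np.roll(w, 1, axis=0)[:, :, 1:nz + 1])
            adv = (np.where(u > 0, dudx_b, dudx_f) * u
                   + np.where(v_at_u > 0, dudy_b, dudy_f) * v_at_u
                   + np.where(w_at_u > 0, dudz_b, dudz_f) * w_at_u)
            lap = ((np.roll(u, -1, axis=0) - 2 * u + np.roll(u, 1, axis=0)) / h ** 2
                   + (upy[:, 2:, :] - 2 * u + upy[:, :-2, :]) / h ** 2
                   + (upz[:, :, 2:] - 2 * u + upz[:, :, :-2]) / h ** 2)
            un[:] = u + dt * (nu * lap - adv)
        return un, vn, wn

    def _project(self, u, v, w, dt):
        g = self.grid
        h = g.h
        div = ((v[:, 1:, :] - v[:, :-1, :]) / h
               + (w[:, :, 1:] - w[:, :, :-1]) / h)
        if g.nx > 1:
            div = div + (np.roll(u, -1, axis=0) - u) / h
        rhs = div[self.fluid] / dt
        pvec = self._lu.solve(rhs)
        if not np.all(np.isfinite(pvec)):
            raise SolverError("pressure solve returned non-finite values")
        p = np.zeros(g.shape)
        p[self.fluid] = pvec
        # gradient correction on open faces
        gy = (p[:, 1:, :] - p[:, :-1, :]) / h
        v[:, 1:-1, :][self.v_corr[:, 1:-1, :]] -= dt * gy[self.v_corr[:, 1:-1, :]]
        v[:, -1, :][self.outlet_fluid] -= dt * (0.0 - p[:, -1, :][self.outlet_fluid]) / h
        gz = (p[:, :, 1:] - p[:, :, :-1]) / h
        w[:, :, 1:-1][self.w_corr[:, :, 1:-1]] -= dt * gz[self.w_corr[:, :, 1:-1]]
        if g.nx > 1:
            gx = (p - np.roll(p, 1, axis=0)) / h
            u[self.u_corr] -= dt * gx[self.u_corr]
        return p

    # ------------------------------------------------------------------
    def advance(self, flow: FlowField, dt_total: float, t0: float,
                inflow_speed=None) -> FlowField:
        """Advance by ``dt_total`` (one coupling interval), substepping to
        satisfy the advective and diffusive stability limits.

        ``inflow_speed``: constant speed (mm/s); if None, evaluated from the
        sawtooth waveform at each substep time.
        """
        u, v, w = flow.u.copy(), flow.v.copy(), flow.w.copy()
        vmax = max(flow.max_speed(), self.cfg.peak_inflow * 1.7, 1e-9)
        dt_sub = self.stable_dt(vmax)
        n_sub = max(int(np.ceil(dt_total / dt_sub)), 1)
        if n_sub > 200000:
            raise SolverError(
                f"advective/diffusive stability requires {n_sub} substeps per "
                f"coupling interval; grid or time step is unreasonable")
        dt = dt_total / n_sub
        p = flow.p
        for m in range(n_sub):
            t = t0 + m * dt
            speed = (inflow_speed if inflow_speed is not None
                     else float(inflow_profile(t, self.cfg)))
            vin = speed * self.inlet_template
            self._apply_bcs(u, v, w, vin)
            u, v, w = self._advect_diffuse(u, v, w, dt)
            self._apply_bcs(u, v, w, vin)
            p = self._project(u, v, w, dt)
            v[self.v_zero] = 0.0
            w[self.w_zero] = 0.0
            if self.grid.nx > 1:
                u[self.u_zero] = 0.0
        out = FlowField(grid=flow.grid, solid=flow.solid, u=u, v=v, w=w, p=p,
                        t=t0 + dt_total, solver=self)
        return out


# ======================================================================
# Public operations
# ======================================================================

def _get_solver(flow: FlowField, cfg: SimulationConfig) -> ProjectionSolver:
    s = flow.solver
    if s is None or s.grid is not flow.grid:
        flow.solver = ProjectionSolver(flow.grid, flow.solid, cfg)
    elif s.cfg is not cfg:
        flow.solver = s.rebind(cfg)
    return flow.solver


def step_flow(flow: FlowField, cfg: SimulationConfig, t: float,
              inflow_speed=None) -> FlowField:
    """Advance the flow by one coupling step ``cfg.dt`` starting at time t."""
    solver = _get_solver(flow, cfg)
    return solver.advance(flow, cfg.dt, t, inflow_speed=inflow_speed)


def steady_solve(cfg: SimulationConfig, geometry: Geometry,
                 inflow_speed: float, *, grid: Grid | None = None,
                 tol: float = 1.0e-6, max_steps: int = 5000,
                 init: FlowField | None = None) -> FlowField:
    """Iterate to the steady field under constant inflow.

    Convergence criterion: maximum field change per coupling step below
    ``tol`` times the field scale.  ``init`` provides a warm start (e.g. the
    converged field at a nearby inflow level).  Raises :class:`SolverError`
    with the residual history on failure.
    """
    if inflow_speed < 0:
        raise ValueError("inflow_speed must be >= 0")
    from .scenario import build_grid
    if init is not None:
        g, solid, solver = init.grid, init.solid, init.solver
        if solver is None:
            solver = ProjectionSolver(g, solid, cfg)
    else:
        g = grid or build_grid(cfg, geometry)
        solid = solid_mask(geometry, g)
        solver = ProjectionSolver(g, solid, cfg)
    flow = FlowField.zeros(g, solid) if init is None else init.copy()
    flow.solver = solver
    if inflow_speed == 0.0 and init is None:
        return flow
    if init is None:
        # warm start from the inlet profile extruded downstream
        flow.v[:, :, :] = inflow_speed * solver.inlet_template[:, None, :]
        flow.v[solver.v_zero] = 0.0
    history = []
    for it in range(max_steps):
        new = solver.advance(flow, cfg.dt, 0.0, inflow_speed=inflow_speed)
        scale = max(new.max_speed(), 1e-12)
        res = max(float(np.max(np.abs(new.v - flow.v))),
                  float(np.max(np.abs(new.w - flow.w)))) / scale
        history.append(res)
        flow = new
        if res < tol:
            return flow
    raise SolverError(
        f"steady_solve did not converge below {tol} in {max_steps} steps; "
        f"last residuals {history[-5:]}")


def vz_wall_map(flow: FlowField, z_probe: float = 0.001,
                geometry: Geometry | None = None):
    """Wall-normal velocity sampled ``z_probe`` above the local wall.

    Returns ``(y_centers, vz)`` with ``vz`` of shape (nx, ny); negative
    values point toward the wall.  ``geometry`` supplies the local wall
    height (strut caps, cavity floors); without it the wall is z = 0.
    """
    g = flow.grid
    y = g.yc
    # discrete local wall: top face of the highest solid cell in each column
    # (the staircase surface the flow actually sees); z0 where none is solid.
    # The map plane never dips below the nominal wall level z=0, so over a
    # defect cavity the probe stays at the vessel-wall plane (the map is a
    # planar x-y view, not a surface-following one).
    any_solid = flow.solid.any(axis=2)
    ktop = g.nz - 1 - np.argmax(flow.solid[:, :, ::-1], axis=2)
    wall_h = np.where(any_solid, g.z0 + (ktop + 1) * g.h, g.z0)
    wall_h = np.maximum(wall_h, 0.0)
    z_s = wall_h + z_probe                      # (nx, ny)
    if np.any(z_s >= g.z_max):
        raise ValueError("z_probe above the domain for some columns")
    # interpolate w (on z-faces) linearly in z at each column
    gz = (z_s - g.z0) / g.h
    k0 = np.clip(np.floor(gz).astype(int), 0, g.nz - 1)
    fz = gz - k0
    cols = np.arange(g.ny)[None, :]
    rows = np.arange(g.nx)[:, None]
    vz = ((1 - fz) * flow.w[rows, cols, k0] + fz * flow.w[rows, cols, k0 + 1])
    kc = np.clip(k0, 0, g.nz - 1)
    if np.any(flow.solid[rows, cols, kc] & (z_s > wall_h + g.h)):
        raise ValueError("z_probe lies inside solid for some columns")
    return y, vz


def toward_wall_band_averages(flow: FlowField, geometry: Geometry,
                              z_probe: float = 0.001):
    """Mean toward-wall |Vz| in bands one strut diameter wide immediately
    upstream/downstream of each strut.  Returns list of (up, down) pairs."""
    y, vz = vz_wall_map(flow, z_probe, geometry)
    toward = np.maximum(-vz, 0.0).mean(axis=0)  # average over x
    d = 2 * geometry.strut_radius
    out = []
    for yc in geometry.strut_y:
        up = (y >= yc - geometry.strut_radius - d) & (y < yc - geometry.strut_radius)
        dn = (y > yc + geometry.strut_radius) & (y <= yc + geometry.strut_radius + d)
        out.append((float(toward[up].mean()), float(toward[dn].mean())))
    return out


def interp_velocity(flow: FlowField, points: np.ndarray) -> np.ndarray:
    """Interpolate (u, v, w) at arbitrary points, shape (N, 3), mm/s.

    Per-component bilinear (2-D) / trilinear (3-D, periodic in x)
    interpolation on the staggered locations.  Points outside the grid are
    clamped to the boundary values.
    """
    g = flow.grid
    h = g.h
    pts = np.asarray(points, dtype=float)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    out = np.zeros_like(pts)
    if g.nx == 1 and _HAVE_NUMBA:
        _interp2d_vw(flow.v[0], flow.w[0], np.ascontiguousarray(y),
                     np.ascontiguousarray(z), g.y0, g.z0, h, g.ny, g.nz, out)
        return out

    def lin_index(coord, origin, n, offset):
        gg = (coord - origin) / h - offset
        i0 = np.floor(gg).astype(int)
        f = gg - i0
        i0c = np.clip(i0, 0, n - 2) if n >= 2 else np.zeros_like(i0)
        f = np.clip(gg - i0c, 0.0, 1.0)
        return i0c, f

    if g.nx > 1:
        def x_index(offset):
            gg = (x - g.x0) / h - offset
            i0 = np.floor(gg).astype(int)
            f = gg - i0
            return i0 % g.nx, (i0 + 1) % g.nx, f
    # v: (x_c, y_face, z_c)
    j0, fy = lin_index(y, g.y0, g.ny + 1, 0.0)
    k0, fz = lin_index(z, g.z0, g.nz, 0.5)
    if g.nx == 1:
        varr = flow.v[0]
        out[:, 1] = ((1 - fy) * (1 - fz) * varr[j0, k0]
                     + (1 - fy) * fz * varr[j0, k0 + 1]
                     + fy * (1 - fz) * varr[j0 + 1, k0]
                     + fy * fz * varr[j0 + 1, k0 + 1])
    else:
        ia, ib, fx = x_index(0.5)
        varr = flow.v
        out[:, 1] = (
            (1 - fx) * ((1 - fy) * (1 - fz) * varr[ia, j0, k0]
                        + (1 - fy) * fz * varr[ia, j0, k0 + 1]
                        + fy * (1 - fz) * varr[ia, j0 + 1, k0]
                        + fy * fz * varr[ia, j0 + 1, k0 + 1])
            + fx * ((1 - fy) * (1 - fz) * varr[ib, j0, k0]
                    + (1 - fy) * fz * varr[ib, j0, k0 + 1]
                    + fy * (1 - fz) * varr[ib, j0 + 1, k0]
                    + fy * fz * varr[ib, j0 + 1, k0 + 1]))
    # w: (x_c, y_c, z_face)
    j0, fy = lin_index(y, g.y0, g.ny, 0.5)
    k0, fz = lin_index(z, g.z0, g.nz + 1, 0.0)
    if g.nx == 1:
        warr = flow.w[0]
        out[:, 2] = ((1 - fy) * (1 - fz) * warr[j0, k0]
                     + (1 - fy) * fz * warr[j0, k0 + 1]
                     + fy * (1 - fz) * warr[j0 + 1, k0]
                     + fy * fz * warr[j0 + 1, k0 + 1])
    else:
        ia, ib, fx = x_index(0.5)
        warr = flow.w
        out[:, 2] = (
            (1 - fx) * ((1 - fy) * (1 - fz) * warr[ia, j0, k0]
                        + (1 - fy) * fz * warr[ia, j0, k0 + 1]
                        + fy * (1 - fz) * warr[ia, j0 + 1, k0]
                        + fy * fz * warr[ia, j0 + 1, k0 + 1])
            + fx * ((1 - fy) * (1 - fz) * warr[ib, j0, k0]
                    + (1 - fy) * fz * warr[ib, j0, k0 + 1]
                    + fy * (1 - fz) * warr[ib, j0 + 1, k0]
                    + fy * fz * warr[ib, j0 + 1, k0 + 1]))
    # u: (x_face, y_c, z_c); zero in 2-D mode
    if g.nx > 1:
        ia, ib, fx = x_index(0.0)
        j0, fy = lin_index(y, g.y0, g.ny, 0.5)
        k0, fz = lin_index(z, g.z0, g.nz, 0.5)
        uarr = flow.u
        out[:, 0] = (
            (1 - fx) * ((1 - fy) * (1 - fz) * uarr[ia, j0, k0]
                        + (1 - fy) * fz * uarr[ia, j0, k0 + 1]
                        + fy * (1 - fz) * uarr[ia, j0 + 1, k0]
                        + fy * fz * uarr[ia, j0 + 1, k0 + 1])
            + fx * ((1 - fy) * (1 - fz) * uarr[ib, j0, k0]
                    + (1 - fy) * fz * uarr[ib, j0, k0 + 1]
                    + fy * (1 - fz) * uarr[ib, j0 + 1, k0]
                    + fy * fz * uarr[ib, j0 + 1, k0 + 1]))
    return out
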