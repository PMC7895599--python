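"""Coupled flow/platelet time stepping, replenishment and calibration.

Coupling is one-way (flow -> platelets), so the flow is precomputed once per
geometry as a lookup table and replayed for the whole perfusion.  Two table
flavors exist: a quasi-steady ladder of steady solves blended by the
instantaneous inflow (the default; valid because the 30 s inflow ramp is
slow against the ~0.4 s viscous equilibration of the channel patch) and a
fully unsteady recorded waveform period for sub-second pulsation.  Each
coupling step (0.01 s) does: flow lookup, free-platelet advection and
Brownian diffusion, tether attempts, bonded-platelet force balance,
activation, rupture, inlet replenishment, outflow removal and event
logging.  Everything is driven by one seeded random generator, so a run is
bit-reproducible given its seed.
"""

from __future__ import annotations

import json
import sys
import time as _time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import observables
from .adhesion import (FREE, PlateletArrays, activate_arrays,
                       advect_free, attempt_tether_arrays, diffuse_free,
                       resolve_contacts, rupture_check_arrays,
                       update_tethered_arrays)
from .hemodynamics import FlowField, ProjectionSolver
from .scenario import (Geometry, Grid, SimulationConfig, build_geometry,
                       build_grid, inflow_profile, seed_platelets, solid_mask)

EVENT_COLUMNS = ["time_s", "platelet_id", "x_mm", "y_mm", "z_mm",
                 "patch_label", "event"]


class CalibrationError(RuntimeError):
    pass


# ======================================================================
# Periodic flow table
# ======================================================================

@dataclass
class PeriodicFlow:
    """One waveform period of flow snapshots, replayed cyclically."""

    grid: Grid
    solid: np.ndarray
    fields: list            # FlowField per coupling step of the period

    @property
    def n_phases(self) -> int:
        return len(self.fields)

    def at_step(self, n: int) -> FlowField:
        return self.fields[n % self.n_phases]


@dataclass
class QuasiSteadyFlow:
    """Inflow-level ladder of steady fields, blended per coupling step.

    Valid when the waveform varies slowly against the viscous equilibration
    time of the channel (a 30 s ramp against ~0.4 s here): the instantaneous
    field is the steady solution at the instantaneous inflow, obtained by
    linear interpolation between precomputed levels.
    """

    grid: Grid
    solid: np.ndarray
    cfg: SimulationConfig
    speeds: np.ndarray       # ascending inflow levels, mm/s
    levels: list             # FlowField per level
    _cache_n: int = -1
    _cache_field: Optional[FlowField] = None

    def at_step(self, n: int) -> FlowField:
        if n == self._cache_n:
            return self._cache_field
        t = n * self.cfg.dt
        u = float(inflow_profile(t, self.cfg))
        i = int(np.searchsorted(self.speeds, u, side="right")) - 1
        i = max(0, min(i, len(self.speeds) - 2))
        u0, u1 = self.speeds[i], self.speeds[i + 1]
        f = 0.0 if u1 == u0 else (u - u0) / (u1 - u0)
        a, b = self.levels[i], self.levels[i + 1]
        out = FlowField(grid=self.grid, solid=self.solid,
                        u=(1 - f) * a.u + f * b.u,
                        v=(1 - f) * a.v + f * b.v,
                        w=(1 - f) * a.w + f * b.w,
                        p=(1 - f) * a.p + f * b.p, t=t)
        self._cache_n, self._cache_field = n, out
        return out


def compute_flow_table(cfg: SimulationConfig,
                       geometry: Optional[Geometry] = None,
                       grid: Optional[Grid] = None,
                       progress: bool = False):
    """Build the engine's flow lookup for the configured flow model."""
    geometry = geometry or build_geometry(cfg)
    if cfg.flow_model == "unsteady":
        return compute_periodic_flow(cfg, geometry, grid, progress)
    from .hemodynamics import steady_solve
    grid = grid or build_grid(cfg, geometry)
    solid = solid_mask(geometry, grid)
    speeds = np.linspace(0.0, cfg.peak_inflow, max(cfg.n_flow_levels, 2))
    levels = [FlowField.zeros(grid, solid)]
    prev = None
    for u in speeds[1:]:
        prev = steady_solve(cfg, geometry, float(u), grid=grid, init=prev)
        levels.append(prev)
        if progress:
            print(f"[stentflow] steady level U={u:.2f} mm/s done", file=sys.stderr)
    levels[0].solver = levels[1].solver if len(levels) > 1 else None
    return QuasiSteadyFlow(grid=grid, solid=solid, cfg=cfg,
                           speeds=speeds, levels=levels)


def compute_periodic_flow(cfg: SimulationConfig,
                          geometry: Optional[Geometry] = None,
                          grid: Optional[Grid] = None,
                          progress: bool = False) -> PeriodicFlow:
    """Spin the solver up and record one waveform period of snapshots."""
    geometry = geometry or build_geometry(cfg)
    grid = grid or build_grid(cfg, geometry)
    solid = solid_mask(geometry, grid)
    solver = ProjectionSolver(grid, solid, cfg)
    flow = FlowField.zeros(grid, solid)
    flow.solver = solver
    n_phases = max(int(round(cfg.waveform_period / cfg.dt)), 1)
    t = 0.0
    for p in range(cfg.spinup_periods * n_phases):
        flow = solver.advance(flow, cfg.dt, t)
        t += cfg.dt
        if progress and p % n_phases == 0:
            print(f"[stentflow] flow spin-up t={t:.2f}s", file=sys.stderr)
    fields = []
    for p in range(n_phases):
        flow = solver.advance(flow, cfg.dt, t)
        t += cfg.dt
        fields.append(flow)
    if progress:
        print("[stentflow] periodic flow table ready", file=sys.stderr)
    return PeriodicFlow(grid=grid, solid=solid, fields=fields)


# ======================================================================
# Simulation state and stepping
# ======================================================================

@dataclass
class SimulationState:
    cfg: SimulationConfig
    geometry: Geometry
    flow: Optional[PeriodicFlow]
    platelets: PlateletArrays
    rng: np.random.Generator
    t: float = 0.0
    step_index: int = 0
    n_seeded: int = 0
    n_injected: int = 0
    n_exited: int = 0
    next_id: int = 0
    n_tethered_cum: int = 0
    occupancy: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def conservation_residual(self) -> int:
        """(in domain) + (exited) - (injected) - (seeded); zero if platelets
        are conserved."""
        return (len(self.platelets) + self.n_exited
                - self.n_injected - self.n_seeded)


def _log_events(state: SimulationState, idx: np.ndarray, kind: str,
                patches=None) -> None:
    if idx.size == 0:
        return
    arr = state.platelets
    p = patches if patches is not None else arr.bond_patch[idx]
    state.events.append((np.full(idx.size, state.t), arr.id[idx].copy(),
                         arr.pos[idx].copy(), np.asarray(p, dtype=np.int8),
                         kind))


def _inject(state: SimulationState) -> None:
    """Poisson inlet replenishment proportional to the instantaneous flux."""
    cfg = state.cfg
    fl = state.flow.at_step(state.step_index)
    g = fl.grid
    vin = fl.v[:, 0, :]
    if g.nx == 1:
        flux = float(vin.sum()) * g.h * cfg.thickness       # mm^3/s
    else:
        flux = float(vin.sum()) * g.h * g.h
    lam = cfg.platelet_density_mm3 * flux * cfg.dt / cfg.parcel_weight
    n = int(state.rng.poisson(max(lam, 0.0)))
    if n == 0:
        return
    # flux-weighted wall-normal position
    if g.nx == 1:
        wz = np.maximum(vin[0], 0.0)
    else:
        wz = np.maximum(vin, 0.0).mean(axis=0)
    tot = wz.sum()
    if tot <= 0:
        return
    pz = wz / tot
    kz = state.rng.choice(len(pz), size=n, p=pz)
    z = g.z0 + (kz + state.rng.random(n)) * g.h
    speed = np.maximum(wz[kz], 1e-12)
    y = g.y0 + state.rng.random(n) * speed * cfg.dt
    x = state.rng.random(n) * cfg.thickness
    new = PlateletArrays(n)
    new.pos[:, 0] = x
    new.pos[:, 1] = y
    new.pos[:, 2] = z
    new.id[:] = state.next_id + np.arange(n)
    state.next_id += n
    state.n_injected += n
    state.platelets = state.platelets.extend(new)


def _remove_exited(state: SimulationState) -> None:
    arr = state.platelets
    g = state.flow.grid if state.flow is not None else None
    y_max = g.y_max if g is not None else state.cfg.domain_length
    gone = np.flatnonzero((arr.pos[:, 1] > y_max)
                          # bonded platelets never exit (anchored inside)
                          & (arr.state == FREE))
    if gone.size:
        state.n_exited += int(gone.size)
        arr.remove(gone)


def step(state: SimulationState, cfg: Optional[SimulationConfig] = None) -> SimulationState:
    """One coupled update of length ``cfg.dt``; mutates and returns state."""
    cfg = cfg or state.cfg
    arr = state.platelets
    fl = state.flow.at_step(state.step_index)
    advect_free(arr, fl, cfg.dt)
    diffuse_free(arr, cfg, cfg.dt, state.rng)
    resolve_contacts(arr, state.geometry, cfg)
    if cfg.shear_gated_tethering and cfg.peak_inflow > 0:
        rate_factor = float(inflow_profile(state.t, cfg)) / cfg.peak_inflow
    else:
        rate_factor = 1.0
    tethered = attempt_tether_arrays(arr, state.geometry, cfg, state.t,
                                     cfg.dt, state.rng, state.occupancy,
                                     rate_factor=rate_factor)
    state.n_tethered_cum += int(tethered.size)
    _log_events(state, tethered, "tether")
    forces = update_tethered_arrays(arr, fl, cfg, cfg.dt)
    resolve_contacts(arr, state.geometry, cfg)
    activated = activate_arrays(arr, cfg, state.t)
    _log_events(state, activated, "activate")
    ruptured, rpatches = rupture_check_arrays(arr, cfg, cfg.dt, state.rng,
                                              forces, state.occupancy)
    _log_events(state, ruptured, "rupture", patches=rpatches)
    _inject(state)
    _remove_exited(state)
    state.t += cfg.dt
    state.step_index += 1
    return state


# ======================================================================
# Full run
# ======================================================================

@dataclass
class RunResult:
    config: SimulationConfig
    geometry: Geometry
    region: "observables.CountingRegion"
    timeseries: pd.DataFrame
    events: pd.DataFrame
    snapshots: dict
    counters: dict
    flow: Optional[PeriodicFlow] = None

    def density_at(self, t: float) -> float:
        ts = self.timeseries
        i = int(np.argmin(np.abs(ts["time_s"].to_numpy() - t)))
        return float(ts["adhered_per_mm2"].iloc[i])

    def save(self, outdir) -> None:
        from pathlib import Path
        from . import vtkio
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.timeseries.to_csv(out / "timeseries.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        per_strut = observables.per_strut_timeseries(self)
        if per_strut is not None:
            per_strut.to_csv(out / "per_strut.csv", index=False)
        for t, snap in self.snapshots.items():
            observables.snapshot_export_arrays(
                snap, out / f"platelets_t{t:g}s.vtk")
        manifest = {
            "config": json.loads(pd.Series(self.config.__dict__).to_json()),
            "seed": self.config.rng_seed,
            "counters": self.counters,
            "counting_region": {"y0": self.region.y0, "y1": self.region.y1},
            "versions": {"stentflow": "0.1.0", "numpy": np.__version__,
                         "pandas": pd.__version__},
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


def _events_frame(events: list) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    rows = []
    for t, ids, pos, patches, kind in events:
        rows.append(pd.DataFrame({
            "time_s": t, "platelet_id": ids,
            "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2],
            "patch_label": patches, "event": kind}))
    return pd.concat(rows, ignore_index=True)


def run(cfg: SimulationConfig, *, flow: Optional[PeriodicFlow] = None,
        progress: bool = False, keep_flow: bool = False) -> RunResult:
    """Execute the full perfusion and collect observables.

    ``flow`` may carry a precomputed periodic flow table for this config's
    geometry/grid (used to amortize the solver across replicate seeds).
    """
    geometry = build_geometry(cfg)
    region = observables.default_counting_region(cfg, geometry)
    rng = np.random.default_rng(cfg.rng_seed)
    n_steps = int(round(cfg.duration / cfg.dt))
    if flow is None and n_steps > 0:
        flow = compute_flow_table(cfg, geometry, progress=progress)
    seeded = seed_platelets(cfg, geometry, rng)
    n0 = seeded.shape[0]
    arr = PlateletArrays(n0)
    arr.pos[:] = seeded
    arr.id[:] = np.arange(n0)
    state = SimulationState(cfg=cfg, geometry=geometry, flow=flow,
                            platelets=arr, rng=rng, n_seeded=n0, next_id=n0)

    rec_every = max(int(round(cfg.record_interval / cfg.dt)), 1)
    times, dens, cumdens = [], [], []
    snapshots = {}

    def record():
        times.append(state.t)
        dens.append(observables.adhered_density_arrays(
            state.platelets, region, cfg))
        cumdens.append(state.n_tethered_cum * cfg.parcel_weight
                       / region.area(cfg))

    record()
    wall0 = _time.time()
    for n in range(n_steps):
        step(state, cfg)
        if (n + 1) % rec_every == 0:
            record()
        for ts in cfg.snapshot_times:
            if abs(state.t - ts) < 0.5 * cfg.dt and ts not in snapshots:
                snapshots[ts] = {"pos": state.platelets.pos.copy(),
                                 "state": state.platelets.state.copy(),
                                 "active": state.platelets.active.copy()}
        if progress and (n + 1) % int(round(1.0 / cfg.dt)) == 0:
            print(f"[stentflow] t={state.t:.1f}s platelets={len(state.platelets)} "
                  f"adhered/mm2={dens[-1]:.1f} wall={_time.time()-wall0:.0f}s",
                  file=sys.stderr)

    timeseries = pd.DataFrame({"time_s": times, "adhered_per_mm2": dens,
                               "cumulative_tethers_per_mm2": cumdens})
    counters = {"seeded": state.n_seeded, "injected": state.n_injected,
                "exited": state.n_exited, "in_domain": len(state.platelets),
                "conservation_residual": state.conservation_residual()}
    return RunResult(config=cfg, geometry=geometry, region=region,
                     timeseries=timeseries, events=_events_frame(state.events),
                     snapshots=snapshots, counters=counters,
                     flow=flow if keep_flow else None)


# ======================================================================
# Calibration
# ======================================================================

def calibrate(cfg: SimulationConfig, target_density: float,
              at_time: Optional[float] = None, *, tol: float = 0.15,
              bounds=(1e-3, 1e3), max_evals: int = 12,
              flow: Optional[PeriodicFlow] = None, verbose: bool = False):
    """One-scalar calibration of the adhesion on-rate.

    Searches a global multiplier on ``k_on`` (monotone response) until the
    adhered density at ``at_time`` matches ``target_density`` within ``tol``
    (relative).  Returns ``(config, report)`` where config carries the found
    ``kon_scale`` and report holds the evaluation history.
    """
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    at_time = cfg.duration if at_time is None else at_time
    base = cfg.replace(duration=at_time)
    if flow is None:
        flow = compute_flow_table(base)
    history = []

    def f(scale: float) -> float:
        res = run(base.replace(kon_scale=cfg.kon_scale * scale), flow=flow)
        d = res.density_at(at_time)
        history.append((scale, d))
        if verbose:
            print(f"[calibrate] scale={scale:.4g} density={d:.1f}", file=sys.stderr)
        return d

    lo, hi = bounds
    s = 1.0
    d = f(s)
    if abs(d - target_density) <= tol * target_density:
        return cfg.replace(kon_scale=cfg.kon_scale * s), {
            "scale": s, "achieved": d, "history": history}
    # bracket
    if d < target_density:
        s_lo, d_lo = s, d
        s_hi = s
        while d < target_density:
            s_hi = s_hi * 4.0
            if s_hi > hi:
                raise CalibrationError(
                    f"target {target_density} unreachable below scale {hi}; "
                    f"history={history}")
            d = f(s_hi)
            if d >= target_density:
                break
            s_lo, d_lo = s_hi, d
        d_hi = d
    else:
        s_hi, d_hi = s, d
        s_lo = s
        while d >= target_density:
            s_lo = s_lo / 4.0
            if s_lo < lo:
                raise CalibrationError(
                    f"target {target_density} unreachable above scale {lo}; "
                    f"history={history}")
            d = f(s_lo)
            if d < target_density:
                break
            s_hi, d_hi = s_lo, d
        d_lo = d
    # bisection in log space
    best_s, best_d = min(history, key=lambda sd: abs(sd[1] - target_density))
    while len(history) < max_evals:
        s_mid = float(np.sqrt(s_lo * s_hi))
        d_mid = f(s_mid)
        if abs(d_mid - target_density) < abs(best_d - target_density):
            best_s, best_d = s_mid, d_mid
        if abs(d_mid - target_density) <= tol * target_density:
            break
        if d_mid < target_density:
            s_lo = s_mid
        else:
            s_hi = s_mid
    return cfg.replace(kon_scale=cfg.kon_scale * best_s), {
        "scale": best_s, "achieved": best_d, "history": history}
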