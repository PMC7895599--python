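"""Reported quantities: areal adhesion densities, per-strut partitions,
wall-normal velocity maps and snapshot exports.

Densities are counts of ADHERED parcels (optionally also TETHERED ones)
whose wall-projected position falls in a counting region, multiplied by the
parcel weight and divided by the region's wall-footprint area in mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .adhesion import ADHERED, TETHERED, PlateletArrays
from .scenario import Geometry, SimulationConfig


@dataclass
class CountingRegion:
    """Wall-footprint rectangle [y0, y1] spanning the full transverse width."""

    y0: float
    y1: float

    def __post_init__(self):
        if not self.y1 > self.y0:
            raise ValueError("counting region must have y1 > y0")

    def area(self, cfg: SimulationConfig) -> float:
        return (self.y1 - self.y0) * cfg.thickness

    def contains(self, y) -> np.ndarray:
        y = np.asarray(y)
        return (y >= self.y0) & (y <= self.y1)


@dataclass
class AdhesionRecord:
    """Per-time adhesion bookkeeping for one or more named regions."""

    time: float
    counts: dict
    areas: dict

    @property
    def density(self) -> dict:
        return {k: self.counts[k] / self.areas[k] for k in self.counts}


def default_counting_region(cfg: SimulationConfig,
                            geometry: Geometry) -> CountingRegion:
    """From one strut diameter upstream of the first strut to five diameters
    downstream of the last (the full footprint when there are no struts)."""
    if geometry.n_struts == 0:
        return CountingRegion(0.0, cfg.domain_length)
    d = 2 * geometry.strut_radius
    y0 = (geometry.strut_y.min() - geometry.strut_radius
          - cfg.region_upstream_diameters * d)
    y1 = (geometry.strut_y.max() + geometry.strut_radius
          + cfg.region_downstream_diameters * d)
    return CountingRegion(max(y0, 0.0), min(y1, cfg.domain_length))


def _counted_states(cfg: SimulationConfig):
    return (TETHERED, ADHERED) if cfg.count_tethered else (ADHERED,)


def adhered_density_arrays(arr: PlateletArrays, region: CountingRegion,
                           cfg: SimulationConfig) -> float:
    """Areal density (count/mm^2) of adhered parcels in the region."""
    if region.area(cfg) <= 0:
        raise ValueError("zero-area counting region")
    m = np.isin(arr.state, _counted_states(cfg))
    m &= region.contains(arr.pos[:, 1])
    return float(m.sum()) * cfg.parcel_weight / region.area(cfg)


def adhered_density(state, region: CountingRegion,
                    cfg: Optional[SimulationConfig] = None) -> float:
    """Density from a SimulationState or a PlateletArrays collection."""
    if hasattr(state, "platelets"):
        return adhered_density_arrays(state.platelets, region,
                                      cfg or state.cfg)
    return adhered_density_arrays(state, region, cfg)


def per_strut_partition(state, geometry: Optional[Geometry] = None,
                        cfg: Optional[SimulationConfig] = None) -> dict:
    """Densities in bands one strut diameter wide immediately upstream and
    downstream of each strut; keys are strut indices."""
    if hasattr(state, "platelets"):
        arr, geometry, cfg = state.platelets, state.geometry, state.cfg
    else:
        arr = state
    if geometry is None or geometry.n_struts == 0:
        raise ValueError("per_strut_partition needs at least one strut")
    d = 2 * geometry.strut_radius
    R = geometry.strut_radius
    m = np.isin(arr.state, _counted_states(cfg))
    y = arr.pos[:, 1]
    out = {}
    for i, yc in enumerate(geometry.strut_y):
        up = CountingRegion(yc - R - d, yc - R)
        dn = CountingRegion(yc + R, yc + R + d)
        out[i] = {
            "upstream": float((m & up.contains(y)).sum()) * cfg.parcel_weight / up.area(cfg),
            "downstream": float((m & dn.contains(y)).sum()) * cfg.parcel_weight / dn.area(cfg),
        }
    return out


def per_strut_timeseries(result) -> Optional[pd.DataFrame]:
    """Per-strut band densities at each stored snapshot time."""
    if result.geometry.n_struts == 0 or not result.snapshots:
        return None
    rows = []
    for t, snap in sorted(result.snapshots.items()):
        arr = PlateletArrays(len(snap["state"]))
        arr.pos[:] = snap["pos"]
        arr.state[:] = snap["state"]
        part = per_strut_partition(arr, result.geometry, result.config)
        for i, v in part.items():
            rows.append({"time_s": t, "strut_index": i,
                         "upstream_per_mm2": v["upstream"],
                         "downstream_per_mm2": v["downstream"]})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Snapshot export
# ----------------------------------------------------------------------

def snapshot_export_arrays(snap: dict, path) -> Path:
    """Write one platelet snapshot (positions + state labels) as VTK points."""
    from . import vtkio
    path = Path(path)
    vtkio.write_polydata_points(
        path, snap["pos"],
        {"state": snap["state"].astype(float),
         "adhered": (snap["state"] == ADHERED).astype(float)})
    return path


def snapshot_export(state, path) -> list:
    """Write platelet positions/states and the geometry surface as VTK.

    ``state`` is a SimulationState (or any object with ``platelets``,
    ``geometry`` and ``flow``).  Returns the list of files written.
    """
    from . import vtkio
    path = Path(path)
    arr = state.platelets
    files = [snapshot_export_arrays(
        {"pos": arr.pos, "state": arr.state, "active": arr.active}, path)]
    if state.flow is not None:
        surf = path.with_name(path.stem + "_surfaces.vtk")
        vtkio.write_mask_surface(surf, state.flow.solid, state.flow.grid)
        files.append(surf)
    return files
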