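"""Ready-made configurations.

``desk_scale`` is the package's reference desk-top problem size: a 2-D
near-wall channel patch (2 mm long, 0.6 mm high, 0.1 mm represented
thickness) around two struts, gridded at one sixth of the strut diameter.
It keeps a full 30 s perfusion plus replicates within minutes on one CPU
while preserving the physical parameters of the full-scale setup (strut
size, waveform, platelet density, coupling step).
"""

from __future__ import annotations

from .scenario import SimulationConfig

# One-scalar on-rate calibration of the no-defect arm at desk scale
# (see engine.calibrate); with-defect runs inherit it unchanged.
DESK_KON_SCALE = 1.0


def desk_scale(defects: bool = False, seed: int = 0,
               duration: float = 30.0, **overrides) -> SimulationConfig:
    """Scaled-down 2-strut scenario used by tests and the acceptance runs."""
    kw = dict(
        mode="2d",
        domain_length=2.0,
        domain_height=0.6,
        slab_thickness=0.1,
        first_strut_y=0.7,
        strut_spacing=0.5,
        n_struts=2,
        grid_spacing=0.09144 / 6,
        defects_present=defects,
        rng_seed=seed,
        duration=duration,
        kon_scale=DESK_KON_SCALE,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def single_strut_small(defects: bool = False, seed: int = 0,
                       duration: float = 2.0, **overrides) -> SimulationConfig:
    """Minimal one-strut scenario for fast exercising of the full loop."""
    kw = dict(
        mode="2d",
        domain_length=1.2,
        domain_height=0.35,
        slab_thickness=0.05,
        first_strut_y=0.45,
        n_struts=1,
        grid_spacing=0.09144 / 6,
        defects_present=defects,
        rng_seed=seed,
        duration=duration,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)
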