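"""Canonical simulation scenarios used for validation.

These configs encode, at desk scale, the experimental designs the
simulator is meant to emulate: bioparticle-dose titrations, uptake-rate
modulation by inhibitors or opsonins (a multiplicative rate modifier),
and long-term kinetics.  They are deliberately frozen: validation
results are only comparable when everyone runs the same conditions.

The rate-recovery and dose scenarios use a sparse-event regime
(low per-cell engulfment rate, large field, well-spread cells) because
the object-count metric is only a faithful event counter while multiple
engulfments per cell are rare — exactly as in the real assay, where
object counts saturate once phagosomes crowd each cell.
"""

from __future__ import annotations

from phagoquant.phagosim import SimConfig, derive_seed

__all__ = [
    "rate_modifier_config",
    "dose_config",
    "DOSE_LEVELS",
]

#: bioparticle concentrations spanning the saturation curve (half-sat 100)
DOSE_LEVELS: tuple[float, ...] = (10.0, 50.0, 100.0, 200.0, 400.0)

#: sparse-event base design: ~0.75 expected engulfments per cell per hour
#: at the reference 200 ug/ml dose, 150 cells in a ~0.9 x 0.9 mm field
_SPARSE = SimConfig(
    field_px=(448, 448),
    pixel_size_um=2.0,
    n_cells=150,
    cell_radius_um=20.0,
    base_rate_per_cell_per_min=0.0125,
    seed=0,
)


def rate_modifier_config(
    modifier: float, seed: int, endpoint_only: bool = True, **overrides
) -> SimConfig:
    """Well config for the inhibitor/opsonin rate-modulation design.

    ``modifier`` scales the per-cell engulfment rate (1.0 = vehicle,
    0.3 = a strong inhibitor, 2.0 = an opsonized meal).  With
    ``endpoint_only`` only the 60-min frame is rendered, which is all
    endpoint normalization needs.
    """
    cfg = _SPARSE.replace(
        rate_modifier=modifier,
        seed=derive_seed(seed, "rate", f"{modifier:g}"),
        **overrides,
    )
    if endpoint_only:
        cfg = cfg.replace(frame_times_min=(cfg.duration_min,))
    return cfg


def dose_config(
    particle_conc: float, seed: int, endpoint_only: bool = True, **overrides
) -> SimConfig:
    """Well config for the bioparticle-titration design."""
    cfg = _SPARSE.replace(
        field_px=(320, 320),
        n_cells=60,
        particle_conc=particle_conc,
        seed=derive_seed(seed, "dose", f"{particle_conc:g}"),
        **overrides,
    )
    if endpoint_only:
        cfg = cfg.replace(frame_times_min=(cfg.duration_min,))
    return cfg
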