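"""Fraction-dose registration and voxel-wise accumulation.

Fraction dose grids are mapped to the planning frame by (optionally) a rigid
shift and a deformation vector field, scaled to single-fraction level, and
summed with integer weights (a weekly scan may stand in for the fractions of
its week).  All resampling is pull-back trilinear interpolation: the output
at reference position x samples the input at x + displacement(x); positions
outside the input grid contribute 0 Gy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import DeformationField, DoseGrid, same_lattice

__all__ = [
    "FractionRecord",
    "rigid_shift_dose",
    "warp_dose",
    "scale_to_fraction",
    "accumulate",
]


@dataclass
class FractionRecord:
    """One imaged treatment session and the transforms mapping it to planning.

    ``n_fractions_represented`` is the number of delivered fractions this
    record stands for (weekly imaging: typically 5); weights are explicit,
    never inferred.
    """

    index: int
    dose: DoseGrid
    week: int = 0
    dvf: DeformationField | None = None
    rigid_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_fractions_represented: int = 1

    def __post_init__(self) -> None:
        if self.n_fractions_represented < 1:
            raise ValueError("n_fractions_represented must be >= 1")
        shift = np.asarray(self.rigid_shift, dtype=float)
        if shift.shape != (3,) or not np.all(np.isfinite(shift)):
            raise ValueError("rigid_shift must be a finite 3-vector (mm)")
        self.rigid_shift = tuple(shift)


def _resample(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    out = ndimage.map_coordinates(values, coords, order=1, mode="constant", cval=0.0)
    # trilinear interpolation of non-negative data is non-negative up to rounding
    return np.clip(out, 0.0, None)


def rigid_shift_dose(dose: DoseGrid, shift) -> DoseGrid:
    """Resample a dose grid onto its own lattice translated by ``shift`` (mm).

    ``output(x) = dose(x + shift)``; trilinear, outside-grid reads 0 Gy.
    """
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (3,) or not np.all(np.isfinite(shift)):
        raise ValueError("shift must be a finite 3-vector (mm)")
    if np.all(shift == 0):
        return DoseGrid(dose.values.copy(), dose.spacing, dose.origin)
    idx = np.indices(dose.shape, dtype=float)
    offset = shift / np.asarray(dose.spacing)
    coords = idx + offset[:, None, None, None]
    return DoseGrid(_resample(dose.values, coords), dose.spacing, dose.origin)


def warp_dose(dose: DoseGrid, dvf: DeformationField) -> DoseGrid:
    """Pull a dose grid back through a deformation field.

    The output lives on the reference lattice of ``dvf``:
    ``output(x) = dose(x + dvf(x))``.  The dose grid must share the field's
    spacing; origins may differ and are accounted for.
    """
    if not np.allclose(dose.spacing, dvf.spacing):
        raise ValueError("dose grid and deformation field must share voxel spacing")
    if tuple(dose.shape) != tuple(dvf.shape):
        raise ValueError("dose grid and deformation field must share lattice shape")
    spacing = np.asarray(dvf.spacing)
    idx = np.indices(dvf.shape, dtype=float)
    origin_offset = (np.asarray(dvf.origin) - np.asarray(dose.origin)) / spacing
    coords = np.empty_like(idx)
    for d in range(3):
        coords[d] = idx[d] + dvf.displacements[..., d] / spacing[d] + origin_offset[d]
    return DoseGrid(_resample(dose.values, coords), dvf.spacing, dvf.origin)


def scale_to_fraction(dose: DoseGrid, plan_total_fractions: int) -> DoseGrid:
    """Divide a full-course dose grid by the planned number of fractions."""
    if int(plan_total_fractions) < 1:
        raise ValueError("plan_total_fractions must be >= 1")
    return DoseGrid(dose.values / int(plan_total_fractions), dose.spacing, dose.origin)


def accumulate(
    fractions: list[FractionRecord],
    reference: DoseGrid,
    *,
    plan_total_fractions: int | None = None,
    on_weight_mismatch: str = "warn",
) -> DoseGrid:
    """Delivered-dose grid: weighted sum of registered fraction doses.

    Each record's dose is rigidly shifted, scaled to single-fraction level by
    ``plan_total_fractions`` (default: the sum of record weights), warped to
    the reference frame, and added ``n_fractions_represented`` times.  If the
    weights do not sum to the plan's fraction count the configured policy
    applies ("warn", "error" or "ignore").
    """
    if not fractions:
        raise ValueError("no fraction records to accumulate")
    if on_weight_mismatch not in ("warn", "error", "ignore"):
        raise ValueError("on_weight_mismatch must be 'warn', 'error' or 'ignore'")
    weight_sum = sum(f.n_fractions_represented for f in fractions)
    n_total = weight_sum if plan_total_fractions is None else int(plan_total_fractions)
    if weight_sum != n_total:
        msg = (
            f"fraction weights sum to {weight_sum} but the plan has "
            f"{n_total} fractions"
        )
        if on_weight_mismatch == "error":
            raise ValueError(msg)
        if on_weight_mismatch == "warn":
            warnings.warn(msg, stacklevel=2)
    acc = np.zeros(reference.shape, dtype=float)
    for rec in fractions:
        d = rigid_shift_dose(rec.dose, rec.rigid_shift)
        d = scale_to_fraction(d, n_total)
        if rec.dvf is not None:
            d = warp_dose(d, rec.dvf)
        elif tuple(d.shape) != tuple(reference.shape):
            raise ValueError("fraction dose without a DVF must share the reference lattice")
        acc += rec.n_fractions_represented * d.values
    return DoseGrid(acc, reference.spacing, reference.origin)
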