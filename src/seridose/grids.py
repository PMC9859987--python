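"""Voxel-lattice containers: dose grids, organ masks, deformation fields.

All volumes live on axis-aligned regular lattices. World coordinates follow
the voxel-centre convention ``x = origin + index * spacing`` with 0-based
indices; spacing and origin are in millimetres, dose in gray (Gy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "StructureMask", "DeformationField", "same_lattice"]


def _as_triple(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.broadcast_to(x, (3,)))
    if not all(np.isfinite(t)):
        raise ValueError(f"{name} must be finite, got {t}")
    return t


@dataclass
class DoseGrid:
    """A 3-D absorbed-dose distribution on a regular lattice.

    Parameters
    ----------
    values
        3-D array of dose in Gy; non-negative and finite.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing is in mm)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass
class StructureMask:
    """Boolean organ segmentation on the same lattice as its dose grid."""

    values: np.ndarray
    label: str = ""
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask values must be a 3-D array")
        if not self.values.any():
            raise ValueError(f"mask {self.label!r} selects no voxels")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def volume_cc(self) -> float:
        """Total segmented organ volume (the V_ref of the seriality model)."""
        return float(self.values.sum()) * self.voxel_volume_cc


@dataclass
class DeformationField:
    """Displacement vectors (mm) on the reference lattice.

    ``displacements[i, j, k]`` maps the reference voxel-centre world position
    to the corresponding position in the fraction image:
    ``x_fraction = x_reference + displacements[i, j, k]``.
    """

    displacements: np.ndarray  # shape (nx, ny, nz, 3)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    @classmethod
    def identity(cls, shape, spacing=(3.0, 3.0, 3.0), origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        return cls(np.zeros((*shape, 3)), spacing=spacing, origin=origin)


def same_lattice(a, b, *, atol: float = 1e-9) -> bool:
    """True when two volumes share shape, spacing and origin."""
    return (
        tuple(a.shape) == tuple(b.shape)
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )
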