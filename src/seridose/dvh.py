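"""Dose-volume histograms and the dose-volume metrics used for plan evaluation.

Cumulative DVHs use the "volume receiving at least dose d" convention with the
first bin edge at 0 Gy, fractions relative to the whole segmented organ.
Differential DVHs carry the fractional sub-volumes Δv_i per dose bin that the
relative seriality model consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .grids import DoseGrid, StructureMask, same_lattice

__all__ = [
    "CumulativeDVH",
    "DifferentialDVH",
    "dvh_from_dose",
    "differential_from_cumulative",
    "cumulative_from_differential",
    "dose_metric",
    "d_mean",
    "dose_to_hottest_cc",
    "volume_above_gy",
]

DEFAULT_BIN_WIDTH_GY = 0.1  # fine relative to the 1.8 Gy fraction dose


@dataclass
class CumulativeDVH:
    """Cumulative DVH: fraction of organ receiving >= each bin-edge dose."""

    bin_edges: np.ndarray  # Gy, strictly increasing, first edge 0
    volume_fraction: np.ndarray  # non-increasing, starts at 1
    organ_volume_cc: float
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.bin_edges.shape != self.volume_fraction.shape or self.bin_edges.ndim != 1:
            raise ValueError("bin_edges and volume_fraction must be matching 1-D arrays")
        if self.bin_edges.size < 2:
            raise ValueError("a DVH needs at least two bin edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.bin_edges[0] < 0:
            raise ValueError("bin edges must be non-negative")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative volume fractions must be non-increasing")
        if abs(self.volume_fraction[0] - 1.0) > 1e-9:
            raise ValueError("volume fraction at the first edge must be 1")
        if self.volume_fraction[-1] < -1e-12:
            raise ValueError("volume fractions must be non-negative")
        if not self.organ_volume_cc > 0:
            raise ValueError("organ volume must be positive")


@dataclass
class DifferentialDVH:
    """Differential DVH: fractional sub-volume Δv_i per dose-bin centre D_i."""

    bin_dose: np.ndarray  # Gy, bin centres, increasing
    frac_volume: np.ndarray  # Δv_i, sums to 1
    organ_volume_cc: float
    label: str = ""
    bin_edges: np.ndarray | None = None  # optional, for exact round trips

    def __post_init__(self) -> None:
        self.bin_dose = np.asarray(self.bin_dose, dtype=float)
        self.frac_volume = np.asarray(self.frac_volume, dtype=float)
        if self.bin_dose.shape != self.frac_volume.shape or self.bin_dose.ndim != 1:
            raise ValueError("bin_dose and frac_volume must be matching 1-D arrays")
        if np.any(self.bin_dose < 0) or np.any(np.diff(self.bin_dose) <= 0):
            raise ValueError("bin doses must be non-negative and strictly increasing")
        if np.any(self.frac_volume < -1e-12):
            raise ValueError("fractional volumes must be non-negative")
        if abs(self.frac_volume.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"fractional volumes must sum to 1, got {self.frac_volume.sum():.12f}"
            )
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if self.bin_edges.size != self.bin_dose.size + 1:
                raise ValueError("bin_edges must have one more entry than bin_dose")

    @property
    def n_bins(self) -> int:
        return int(self.bin_dose.size)


def dvh_from_dose(
    grid: DoseGrid,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> CumulativeDVH:
    """Cumulative DVH of the masked voxels of a dose grid.

    The organ volume is ``count(mask) * voxel_volume``; bin edges run from
    0 Gy in steps of ``bin_width`` to just above the maximum masked dose, so
    the last edge always carries volume fraction 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not same_lattice(grid, mask):
        raise ValueError("dose grid and mask do not share a lattice")
    doses = grid.values[mask.values]
    if doses.size == 0:  # pragma: no cover - StructureMask forbids this
        raise ValueError("mask selects no voxels")
    n_bins = int(np.floor(doses.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    sorted_d = np.sort(doses)
    # fraction of voxels with dose >= edge
    below = np.searchsorted(sorted_d, edges, side="left")
    vf = 1.0 - below / doses.size
    return CumulativeDVH(
        bin_edges=edges,
        volume_fraction=vf,
        organ_volume_cc=mask.volume_cc,
        label=mask.label,
    )


def differential_from_cumulative(cdvh: CumulativeDVH) -> DifferentialDVH:
    """Convert cumulative to differential: Δv_i = v(edge_i) − v(edge_{i+1}).

    Any residual volume at or above the last edge is carried in one extra
    trailing bin so that Σ Δv_i = 1 exactly.
    """
    edges = cdvh.bin_edges
    vf = cdvh.volume_fraction
    dv = vf[:-1] - vf[1:]
    centres = 0.5 * (edges[:-1] + edges[1:])
    residual = float(vf[-1])
    if residual > 1e-12:
        width = float(np.mean(np.diff(edges)))
        edges = np.append(edges, edges[-1] + width)
        centres = np.append(centres, 0.5 * (edges[-2] + edges[-1]))
        dv = np.append(dv, residual)
    dv = np.clip(dv, 0.0, None)
    dv = dv / dv.sum()
    return DifferentialDVH(
        bin_dose=centres,
        frac_volume=dv,
        organ_volume_cc=cdvh.organ_volume_cc,
        label=cdvh.label,
        bin_edges=edges,
    )


def cumulative_from_differential(ddvh: DifferentialDVH) -> CumulativeDVH:
    """Inverse of :func:`differential_from_cumulative`.

    Uses the stored bin edges when present; otherwise reconstructs edges as
    midpoints between bin centres (exact for uniform binning).
    """
    if ddvh.bin_edges is not None:
        edges = ddvh.bin_edges
    else:
        c = ddvh.bin_dose
        inner = 0.5 * (c[:-1] + c[1:])
        first = max(0.0, c[0] - (inner[0] - c[0])) if inner.size else max(0.0, c[0] - 0.5)
        last = c[-1] + (c[-1] - inner[-1]) if inner.size else c[-1] + 0.5
        edges = np.concatenate([[first], inner, [last]])
    vf = np.concatenate([[1.0], 1.0 - np.cumsum(ddvh.frac_volume)])
    vf = np.clip(vf, 0.0, 1.0)
    vf[0] = 1.0
    return CumulativeDVH(
        bin_edges=edges,
        volume_fraction=vf,
        organ_volume_cc=ddvh.organ_volume_cc,
        label=ddvh.label,
    )


def d_mean(cdvh: CumulativeDVH) -> float:
    """Mean organ dose, Σ D_i Δv_i over the differential DVH (Gy)."""
    ddvh = differential_from_cumulative(cdvh)
    return float(np.sum(ddvh.bin_dose * ddvh.frac_volume))


def dose_to_hottest_cc(cdvh: CumulativeDVH, x_cc: float) -> float:
    """D_xcc: minimum dose received by the hottest ``x_cc`` cm^3 (Gy).

    Linear interpolation between cumulative-DVH points; on a plateau the
    highest dose with volume fraction >= x/V is returned (the hottest-volume
    reading of the curve).
    """
    if x_cc <= 0:
        raise ValueError("x_cc must be positive")
    if x_cc > cdvh.organ_volume_cc * (1 + 1e-9):
        raise ValueError(
            f"requested volume {x_cc} cc exceeds organ volume {cdvh.organ_volume_cc} cc"
        )
    q = min(x_cc / cdvh.organ_volume_cc, 1.0)
    v = cdvh.volume_fraction
    e = cdvh.bin_edges
    idx = np.nonzero(v >= q)[0]
    i = int(idx[-1])
    if i == v.size - 1 or v[i] <= q + 1e-15:
        return float(e[i])
    # v[i] > q > v[i+1]: interpolate on the falling segment
    return float(e[i] + (v[i] - q) * (e[i + 1] - e[i]) / (v[i] - v[i + 1]))


def volume_above_gy(cdvh: CumulativeDVH, threshold_gy: float) -> float:
    """V_x: percent of the organ receiving at least ``threshold_gy`` (%)."""
    if threshold_gy < 0:
        raise ValueError("dose threshold must be non-negative")
    if threshold_gy > cdvh.bin_edges[-1]:
        return 0.0
    return float(np.interp(threshold_gy, cdvh.bin_edges, cdvh.volume_fraction)) * 100.0


_DCC_RE = re.compile(r"^D([0-9]+(?:\.[0-9]+)?)cc$", re.IGNORECASE)
_VGY_RE = re.compile(r"^V([0-9]+(?:\.[0-9]+)?)$", re.IGNORECASE)


def dose_metric(cdvh: CumulativeDVH, metric: str) -> float:
    """Evaluate a named dose-volume metric on a cumulative DVH.

    ``"Dmean"`` (Gy), ``"D<x>cc"`` e.g. ``"D1cc"``/``"D10cc"`` (Gy), or
    ``"V<t>"`` e.g. ``"V50"`` (% of organ receiving >= t Gy).
    """
    if metric.lower() == "dmean":
        return d_mean(cdvh)
    m = _DCC_RE.match(metric)
    if m:
        return dose_to_hottest_cc(cdvh, float(m.group(1)))
    m = _VGY_RE.match(metric)
    if m:
        return volume_above_gy(cdvh, float(m.group(1)))
    raise ValueError(f"unrecognized dose metric {metric!r}")
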