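"""The relative seriality NTCP model.

Voxel response follows the canonical Poisson (Källman) form

    P(D) = 2^(-exp(e * gamma * (1 - D / D50)))

with D50 the uniform whole-organ dose giving 50% response probability and
gamma the normalized dose-response gradient.  The response to a heterogeneous
dose distribution described by a differential DVH {(D_i, Δv_i)} is

    P_I = [1 - Π_i (1 - P(D_i)^s)^Δv_i]^(1/s)

where s is the relative seriality parameter (s -> 0 parallel-like organ,
s ~ 1 serial-like).  The biologically effective uniform dose (BEUD, D̄̄) is
the uniform whole-organ dose with the same NTCP, obtained by closed-form
inversion of the voxel-response sigmoid.

All heterogeneous-dose evaluation happens in log space so that seriality
parameters as small as 1e-6 (the bladder fit uses s = 1e-4) and as large as
10 are handled without underflow; below ``S_ANALYTIC_LIMIT`` the analytic
s -> 0 limit P_I = exp(-Π_i (-ln P(D_i))^Δv_i) is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .dvh import DifferentialDVH

__all__ = [
    "SerialityParams",
    "NTCPResult",
    "load_default_params",
    "voxel_response",
    "ntcp",
    "ntcp_from_bins",
    "beud_from_ntcp",
    "ntcp_for_volume_fraction",
    "ntcp_result",
]

LN2 = math.log(2.0)
S_ANALYTIC_LIMIT = 1e-8  # below this, use the analytic parallel-organ limit


@dataclass
class SerialityParams:
    """Relative seriality parameter set (D50 in Gy; gamma, s dimensionless)."""

    d50: float
    gamma: float
    s: float
    organ: str = ""
    ci_d50: tuple[float, float] | None = None
    ci_gamma: tuple[float, float] | None = None
    ci_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ValueError("d50 must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.s > 0:
            raise ValueError("s must be positive")
        for name, ci, point in (
            ("ci_d50", self.ci_d50, self.d50),
            ("ci_gamma", self.ci_gamma, self.gamma),
            ("ci_s", self.ci_s, self.s),
        ):
            if ci is not None:
                lo, hi = ci
                if not (lo <= point <= hi):
                    raise ValueError(f"{name}=({lo}, {hi}) does not bracket {point}")


@dataclass
class NTCPResult:
    """NTCP of a dose distribution with its biologically effective uniform dose."""

    ntcp: float
    beud_gy: float
    params_used: SerialityParams


def load_default_params() -> dict[str, SerialityParams]:
    """Bladder and rectum parameter sets shipped with the package.

    Bladder (nocturia, u2): D50 = 80.9 Gy, gamma = 0.44, s = 1e-4 — a
    parallel-like organ.  Rectum (diarrhea, r1): D50 = 67.0 Gy, gamma = 2.5,
    s = 1.0 — serial-like.  Confidence ranges accompany each value.
    """
    text = resources.files("seridose").joinpath("data/seriality_params.yaml").read_text()
    cfg = yaml.safe_load(text)
    out: dict[str, SerialityParams] = {}
    for organ, p in cfg["organs"].items():
        out[organ] = SerialityParams(
            d50=p["d50_gy"],
            gamma=p["gamma"],
            s=p["s"],
            organ=organ,
            ci_d50=tuple(p["d50_ci"]),
            ci_gamma=tuple(p["gamma_ci"]),
            ci_s=tuple(p["s_ci"]),
        )
    return out


def _neg_log_response(dose, d50: float, gamma: float):
    """y(D) = -ln P(D) = ln2 * exp(e*gamma*(1 - D/d50)); 0 means P = 1."""
    with np.errstate(over="ignore", under="ignore"):
        return LN2 * np.exp(np.e * gamma * (1.0 - np.asarray(dose, dtype=float) / d50))


def voxel_response(dose, params: SerialityParams):
    """Response probability P(D) of tissue uniformly irradiated to ``dose`` Gy.

    Strictly increasing in dose with P(D50) = 1/2.  Accepts scalars or arrays.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-_neg_log_response(dose, params.d50, params.gamma))
    return float(out) if out.ndim == 0 else out


def _ntcp_core(y, dv, s: float):
    """NTCP from per-bin y = -ln P and fractional volumes dv (last axis)."""
    y = np.asarray(y, dtype=float)
    dv = np.asarray(dv, dtype=float)
    active = dv > 0
    if s < S_ANALYTIC_LIMIT:
        # parallel limit: P_I = exp(-exp(Σ dv ln y)) ; y = 0 (P = 1) drives
        # the weighted log-sum to -inf only through active bins.
        with np.errstate(divide="ignore"):
            logy = np.log(np.where(active, y, 1.0))
        lg = np.sum(np.where(active, dv * logy, 0.0), axis=-1)
        with np.errstate(over="ignore"):
            return np.exp(-np.exp(lg))
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        # ln(1 - P^s) = ln(-expm1(-s*y)); -inf where P = 1 exactly
        term = np.log(-np.expm1(-s * y))
    log_prod = np.sum(np.where(active, dv * term, 0.0), axis=-1)
    surv = np.exp(log_prod)  # Π (1 - P^s)^dv
    with np.errstate(divide="ignore"):
        return np.exp(np.log1p(-surv) / s)


def ntcp_from_bins(bin_dose, frac_volume, params: SerialityParams, *, s: float | None = None):
    """NTCP from raw DVH bin arrays; broadcasting over leading axes.

    ``bin_dose`` and ``frac_volume`` may be (M,) or (n, M); each row's
    fractional volumes must sum to 1 (padding rows with Δv = 0 is allowed).
    """
    bin_dose = np.asarray(bin_dose, dtype=float)
    frac_volume = np.asarray(frac_volume, dtype=float)
    sums = frac_volume.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("fractional volumes must sum to 1 along the last axis")
    s_val = params.s if s is None else s
    y = _neg_log_response(bin_dose, params.d50, params.gamma)
    out = _ntcp_core(y, frac_volume, s_val)
    return float(out) if np.ndim(out) == 0 else out


def ntcp(ddvh: DifferentialDVH, params: SerialityParams, *, drop_zero_dose_bins: bool = False) -> float:
    """NTCP of a heterogeneous dose distribution (differential DVH).

    ``drop_zero_dose_bins`` removes 0 Gy bins before evaluation (renormalizing
    Δv).  The default retains them: the Poisson sigmoid assigns zero-dose
    tissue a small positive response probability, and for small s dropping
    those bins changes the result.
    """
    dose = ddvh.bin_dose
    dv = ddvh.frac_volume
    if drop_zero_dose_bins:
        keep = dose > 0
        if not keep.any():
            raise ValueError("all bins are at zero dose")
        dose, dv = dose[keep], dv[keep] / dv[keep].sum()
    return float(ntcp_from_bins(dose, dv, params))


def beud_from_ntcp(p: float, params: SerialityParams) -> float:
    """Biologically effective uniform dose D̄̄ for a given NTCP (Gy).

    Closed-form inversion of the voxel-response sigmoid:
    ``D̄̄ = D50 * [1 - (ln(-ln p) - ln ln 2) / (e * gamma)]``, so that a
    uniform whole-organ irradiation at D̄̄ reproduces ``p`` for any s.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("NTCP must lie strictly between 0 and 1 for a finite BEUD")
    d = params.d50 * (1.0 - (math.log(-math.log(p)) - math.log(LN2)) / (np.e * params.gamma))
    if d < 0:
        raise ValueError(
            f"NTCP {p} lies below the zero-dose response floor P(0) of this "
            "parameter set; no non-negative uniform dose produces it"
        )
    return float(d)


def ntcp_result(ddvh: DifferentialDVH, params: SerialityParams) -> NTCPResult:
    """NTCP and its BEUD for one DVH under one parameter set."""
    p = ntcp(ddvh, params)
    return NTCPResult(ntcp=p, beud_gy=beud_from_ntcp(p, params), params_used=params)


def ntcp_for_volume_fraction(dose: float, vol_fraction: float, params: SerialityParams) -> float:
    """Partial-organ response: uniform ``dose`` to a fraction of the organ.

    Literal evaluation of
    ``P_I(D, V) = 1 - [1 - P(D)^s]^((V/V_ref)/s)``;
    note this differs from a 2-bin DVH through the seriality formula unless
    the unirradiated remainder's P(0) term is included there.
    """
    if not 0.0 < vol_fraction <= 1.0:
        raise ValueError("vol_fraction must lie in (0, 1]")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    y = float(_neg_log_response(dose, params.d50, params.gamma))
    s = params.s
    with np.errstate(divide="ignore"):
        term = np.log(-np.expm1(-s * y))  # ln(1 - P^s)
    return float(-np.expm1((vol_fraction / s) * term))
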