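"""Maximum-likelihood fitting of the relative seriality model to a cohort.

Given per-patient differential DVHs and binary responder labels, the Bernoulli
log-likelihood

    l(D50, gamma, s) = Σ_i [y_i ln P_I(dvh_i) + (1 - y_i) ln(1 - P_I(dvh_i))]

is maximized over (D50, gamma, log10 s) with bounded L-BFGS-B from a
multistart grid (the likelihood is multimodal in s, and the two published
organ fits differ in s by four orders of magnitude).  Confidence intervals
come from the profile likelihood at the chi-square(1) quantile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .dvh import DifferentialDVH
from .seriality import SerialityParams, _neg_log_response, _ntcp_core

__all__ = [
    "CohortDataset",
    "FitResult",
    "ProfileInterval",
    "neg_log_likelihood",
    "fit",
    "profile_ci",
    "profile_interval",
    "DEFAULT_BOUNDS",
]

_P_CLAMP = 1e-12
#: optimization bounds for (D50 Gy, gamma, log10 s)
DEFAULT_BOUNDS = ((20.0, 200.0), (0.05, 10.0), (-6.0, 1.0))


@dataclass
class CohortDataset:
    """Per-patient DVHs and responder labels for one organ/symptom.

    ``planned`` (and optionally ``delivered``) are lists of differential
    DVHs, aligned with ``labels`` and ``patient_ids``.
    """

    organ: str
    planned: list[DifferentialDVH]
    labels: np.ndarray
    delivered: list[DifferentialDVH] | None = None
    patient_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.planned) != self.labels.size:
            raise ValueError("one planned DVH per label required")
        if self.delivered is not None and len(self.delivered) != self.labels.size:
            raise ValueError("one delivered DVH per label required")
        if self.patient_ids is None:
            self.patient_ids = [f"p{i:04d}" for i in range(self.labels.size)]

    def __len__(self) -> int:
        return int(self.labels.size)

    def dose_matrix(self, use: str = "planned") -> tuple[np.ndarray, np.ndarray]:
        """Zero-padded (n, M) arrays of bin doses and fractional volumes."""
        dvhs = self.planned if use == "planned" else self.delivered
        if dvhs is None:
            raise ValueError(f"cohort has no {use!r} DVHs")
        m = max(d.n_bins for d in dvhs)
        dose = np.zeros((len(dvhs), m))
        dv = np.zeros((len(dvhs), m))
        for i, d in enumerate(dvhs):
            dose[i, : d.n_bins] = d.bin_dose
            dv[i, : d.n_bins] = d.frac_volume
        return dose, dv


@dataclass
class FitResult:
    params: SerialityParams
    loglik: float
    converged: bool
    n_used: int
    ci_method: str = "none"
    at_bounds: bool = False
    separation_flag: bool = False


@dataclass(frozen=True)
class ProfileInterval:
    low: float
    high: float
    low_at_bound: bool = False
    high_at_bound: bool = False


def _cohort_probs(theta, dose, dv):
    d50, gamma, log10s = theta
    y = _neg_log_response(dose, d50, gamma)
    return _ntcp_core(y, dv, 10.0 ** log10s)


def _nll_from_matrices(theta, dose, dv, labels):
    p = np.clip(_cohort_probs(theta, dose, dv), _P_CLAMP, 1.0 - _P_CLAMP)
    return float(-np.sum(np.where(labels, np.log(p), np.log1p(-p))))


def neg_log_likelihood(
    params: SerialityParams, cohort: CohortDataset, *, use: str = "planned"
) -> float:
    """Negative Bernoulli log-likelihood of a parameter set on a cohort."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    dose, dv = cohort.dose_matrix(use)
    theta = (params.d50, params.gamma, np.log10(params.s))
    return _nll_from_matrices(theta, dose, dv, cohort.labels)


def _start_grid(bounds, n_per_dim=3, rng=None, n_jitter=0):
    fracs = np.linspace(0.15, 0.85, n_per_dim)
    axes = [[lo + f * (hi - lo) for f in fracs] for lo, hi in bounds]
    starts = [np.array(p) for p in itertools.product(*axes)]
    if n_jitter and rng is not None:
        for _ in range(n_jitter):
            starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
    return starts


def fit(
    cohort: CohortDataset,
    init: SerialityParams | None = None,
    bounds=DEFAULT_BOUNDS,
    *,
    use: str = "planned",
    min_per_class: int = 3,
    n_starts_per_dim: int = 3,
    n_jitter_starts: int = 0,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood (D50, gamma, s) for a labeled cohort.

    Runs bounded L-BFGS-B from every point of an ``n_starts_per_dim``^3 grid
    over the bounds (plus ``init`` and optional jittered starts) and keeps the
    best optimum.  A fit ending on a parameter bound is flagged
    (``at_bounds`` / ``separation_flag``) rather than silently returned.
    """
    n_pos = int(cohort.labels.sum())
    n_neg = len(cohort) - n_pos
    if n_pos < min_per_class or n_neg < min_per_class:
        raise ValueError(
            f"need at least {min_per_class} responders and non-responders, "
            f"got {n_pos}/{n_neg}"
        )
    dose, dv = cohort.dose_matrix(use)
    labels = cohort.labels
    obj = lambda th: _nll_from_matrices(th, dose, dv, labels)

    rng = np.random.default_rng(seed)
    starts = _start_grid(bounds, n_starts_per_dim, rng, n_jitter_starts)
    if init is not None:
        starts.append(np.array([init.d50, init.gamma, np.log10(init.s)]))

    best = None
    for x0 in starts:
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    tol = [1e-3 * (hi - lo) for lo, hi in bounds]
    on_bound = [
        theta[i] - bounds[i][0] < tol[i] or bounds[i][1] - theta[i] < tol[i]
        for i in range(3)
    ]
    # s hugging a bound is common and benign (the bladder fit sits at tiny s);
    # D50 or gamma at a bound signals separation / an unidentified curve.
    separation = bool(on_bound[0] or on_bound[1])
    params = SerialityParams(
        d50=float(theta[0]), gamma=float(theta[1]), s=float(10.0 ** theta[2]),
        organ=cohort.organ,
    )
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_used=len(cohort),
        at_bounds=any(on_bound),
        separation_flag=separation,
    )


def profile_interval(
    nll,
    x_hat: np.ndarray,
    index: int,
    bounds,
    level: float = 0.95,
    *,
    rel_step: float = 0.05,
    max_doublings: int = 60,
) -> ProfileInterval:
    """Profile-likelihood interval for one coordinate of a generic objective.

    ``nll`` maps a parameter vector to the negative log-likelihood; the other
    coordinates are re-optimized (warm-started) at each probed value.  Sides
    that never cross the chi-square(1) cutoff before hitting their bound are
    reported at the bound with the corresponding flag set.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    k = x_hat.size
    others_idx = [i for i in range(k) if i != index]
    bounds = [tuple(b) for b in bounds]
    f0 = float(nll(x_hat))
    target = f0 + 0.5 * stats.chi2.ppf(level, df=1)

    warm = {tuple(): None}

    def prof(val, others0):
        if not others_idx:
            full = np.array([val])
            return float(nll(full)), np.empty(0)
        def inner(z):
            full = np.empty(k)
            full[index] = val
            full[others_idx] = z
            return nll(full)
        res = optimize.minimize(
            inner, others0, method="L-BFGS-B",
            bounds=[bounds[i] for i in others_idx],
        )
        return float(res.fun), res.x

    lo_b, hi_b = bounds[index]
    scale = max(abs(x_hat[index]) * rel_step, rel_step * (hi_b - lo_b) * 0.1, 1e-8)
    out = {}
    for side, direction, limit in (("low", -1.0, lo_b), ("high", +1.0, hi_b)):
        others0 = x_hat[others_idx].copy()
        prev_val = float(x_hat[index])
        prev_f = f0
        step = scale
        crossed = False
        at_bound = False
        val = prev_val
        for _ in range(max_doublings):
            val = prev_val + direction * step
            clipped = min(max(val, lo_b), hi_b)
            f, z = prof(clipped, others0)
            if z.size:
                others0 = z
            if f >= target:
                crossed = True
                break
            prev_val, prev_f = clipped, f
            if clipped == limit:
                at_bound = True
                break
            step *= 2.0
        else:
            at_bound = True
        if crossed:
            lo_v, hi_v = sorted((prev_val, min(max(val, lo_b), hi_b)))
            warm_others = {"z": others0.copy()}

            def g(v):
                f, z = prof(v, warm_others["z"])
                if z.size:
                    warm_others["z"] = z
                return f - target

            root = optimize.brentq(g, lo_v, hi_v, xtol=1e-6 * max(1.0, abs(x_hat[index])))
            out[side] = (float(root), False)
        else:
            out[side] = (float(limit), True)
    return ProfileInterval(
        low=out["low"][0],
        high=out["high"][0],
        low_at_bound=out["low"][1],
        high_at_bound=out["high"][1],
    )


_PARAM_INDEX = {"d50": 0, "gamma": 1, "s": 2}


def profile_ci(
    cohort: CohortDataset,
    fit_result: FitResult,
    parameter: str,
    level: float = 0.95,
    *,
    use: str = "planned",
    bounds=DEFAULT_BOUNDS,
) -> ProfileInterval:
    """Profile-likelihood CI for ``"d50"``, ``"gamma"`` or ``"s"``.

    ``s`` is profiled on the log10 scale and the interval returned on the
    natural scale.  Requires a converged fit.
    """
    if not fit_result.converged:
        raise ValueError("profile CI requires a converged fit")
    if parameter not in _PARAM_INDEX:
        raise ValueError(f"unknown parameter {parameter!r}")
    idx = _PARAM_INDEX[parameter]
    dose, dv = cohort.dose_matrix(use)
    labels = cohort.labels
    nll = lambda th: _nll_from_matrices(th, dose, dv, labels)
    p = fit_result.params
    x_hat = np.array([p.d50, p.gamma, np.log10(p.s)])
    iv = profile_interval(nll, x_hat, idx, bounds, level)
    if parameter == "s":
        return ProfileInterval(
            low=10.0 ** iv.low, high=10.0 ** iv.high,
            low_at_bound=iv.low_at_bound, high_at_bound=iv.high_at_bound,
        )
    return iv
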