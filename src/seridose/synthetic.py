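"""Synthetic prostate-RT cohorts: dose grids, organ masks, fractions, PRO scores.

The generator emulates the statistical structure the analysis assumes rather
than anatomy: a central high-dose target with sigmoid penumbra (prescription
40-44 fractions x 1.8 Gy), spherical bladder/rectum surrogates placed so the
cohort's organ mean-dose distribution matches the reported planning moments
(bladder D_mean 44.9 +/- 13.6 Gy, rectum 42.8 +/- 7.3 Gy), smooth random
per-week dose and displacement perturbations standing in for inter-fraction
organ deformation, and 12-month responder labels drawn from the relative
seriality model so that ground truth is known exactly.

All randomness flows through one seed; per-patient substreams are derived
from (seed, patient_index), so any single patient is reproducible without
generating the rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .accumulation import FractionRecord, accumulate
from .dvh import CumulativeDVH, DifferentialDVH, differential_from_cumulative, dvh_from_dose
from .fitting import CohortDataset
from .grids import DeformationField, DoseGrid, StructureMask
from .outcomes import BASELINE, FOLLOWUP_12M, PCSIRecord, ResponderLabel
from .seriality import SerialityParams, load_default_params, ntcp

__all__ = [
    "OrganSpec",
    "CohortSpec",
    "SyntheticPatient",
    "default_cohort_spec",
    "generate_patient",
    "delivered_dose",
    "planned_dvh",
    "delivered_dvh",
    "sample_responses",
    "make_cohort",
]


@dataclass
class OrganSpec:
    """Targets for one organ surrogate: placement and dose-response truth."""

    name: str
    dmean_mu_gy: float
    dmean_sd_gy: float
    direction: tuple[float, float, float]
    radius_range_mm: tuple[float, float] = (6.0, 9.0)
    #: semi-axis multiplier along ``direction``: organs are prolate, straddling
    #: the dose gradient so each DVH spans near-zero to prescription dose
    elongation: float = 2.5
    symptom_id: str = ""
    truth: SerialityParams | None = None

    def __post_init__(self) -> None:
        if self.dmean_sd_gy < 0:
            raise ValueError("dmean_sd_gy must be non-negative")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort (defaults mirror the clinic)."""

    n_patients: int = 46
    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    dose_per_fraction_gy: float = 1.8
    fraction_choices: tuple[int, ...] = (40, 41, 42, 43, 44)
    n_weeks: int = 8
    target_radius_range_mm: tuple[float, float] = (10.0, 14.0)
    penumbra_mm: float = 4.0  # sigmoid falloff scale of the target edge
    #: mid-dose bath: fraction of prescription, extra radius beyond the
    #: target, and falloff scale — the IMRT dose spread around the target
    bath_frac_range: tuple[float, float] = (0.45, 0.60)
    bath_extra_radius_mm: tuple[float, float] = (8.0, 16.0)
    bath_penumbra_mm: float = 8.0
    dose_noise_sd: float = 0.03  # relative, smooth multiplicative field
    displacement_sd_mm: float = 2.0  # RMS of the smooth random DVF
    rigid_shift_sd_mm: float = 1.0  # per-axis setup shift
    organs: tuple[OrganSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for val, name in (
            (self.dose_noise_sd, "dose_noise_sd"),
            (self.displacement_sd_mm, "displacement_sd_mm"),
            (self.rigid_shift_sd_mm, "rigid_shift_sd_mm"),
        ):
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.organs:
            self.organs = _default_organs()

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ {name!r} in spec")


def _default_organs() -> tuple[OrganSpec, ...]:
    truth = load_default_params()
    return (
        OrganSpec(
            name="bladder",
            dmean_mu_gy=44.9,
            dmean_sd_gy=13.6,
            direction=(0.0, 1.0, 0.0),
            radius_range_mm=(5.0, 8.0),
            elongation=1.8,
            symptom_id="u2",
            truth=truth["bladder"],
        ),
        OrganSpec(
            name="rectum",
            dmean_mu_gy=42.8,
            dmean_sd_gy=7.3,
            direction=(0.0, -1.0, 0.0),
            radius_range_mm=(5.0, 7.5),
            elongation=1.8,
            symptom_id="r1",
            truth=truth["rectum"],
        ),
    )


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    return replace(CohortSpec(seed=seed), **overrides) if overrides else CohortSpec(seed=seed)


@dataclass
class SyntheticPatient:
    index: int
    plan: DoseGrid
    masks: dict[str, StructureMask]
    fractions: list[FractionRecord]
    n_fractions: int
    prescription_gy: float


def _world_coords(spec: CohortSpec):
    idx = np.indices(spec.shape, dtype=float)
    sp = np.asarray(spec.spacing)
    return np.stack([idx[d] * sp[d] for d in range(3)], axis=-1)  # origin 0


def _smooth_unit_field(rng, shape, sigma_vox: float = 2.0) -> np.ndarray:
    """Gaussian-smoothed white noise, rescaled to unit RMS."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    rms = float(np.sqrt(np.mean(f**2)))
    return f / rms if rms > 0 else f


def _place_organ(plan_values, coords, centre, organ: OrganSpec, radius, target_mean, max_off=36.0):
    """Offset a prolate organ along its axis so its mean plan dose hits target.

    The organ is an ellipsoid with transverse semi-axis ``radius`` and long
    semi-axis ``radius * elongation`` along its placement direction, so it
    straddles the target's dose gradient.  The mean dose is monotone
    decreasing in the offset; bisection to ~0.1 mm.  The voxelized mean can
    still differ from the target by a fraction of the local dose gradient
    across one voxel.
    """
    direction = np.asarray(organ.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    rel = coords - centre
    long_axis = radius * organ.elongation
    # split rel into components along / transverse to the placement axis
    along = np.sum(rel * direction, axis=-1)
    trans2 = np.sum(rel * rel, axis=-1) - along**2
    # Q(off) = trans^2/r^2 + (along - off)^2/long^2 <= 1
    qa = trans2 / radius**2 + along**2 / long_axis**2
    qb = along / long_axis**2
    qc = 1.0 / long_axis**2

    def mean_at(off):
        m = qa - 2.0 * off * qb + off * off * qc <= 1.0
        return float(plan_values[m].mean()) if m.any() else 0.0

    hi_val, lo_val = mean_at(0.0), mean_at(max_off)
    t = float(np.clip(target_mean, lo_val, hi_val))
    lo, hi = 0.0, max_off
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) >= t:
            lo = mid
        else:
            hi = mid
    off = 0.5 * (lo + hi)
    mask = qa - 2.0 * off * qb + off * off * qc <= 1.0
    return mask, off


def generate_patient(
    spec: CohortSpec, patient_index: int, *, with_fractions: bool = True
) -> SyntheticPatient:
    """One synthetic patient: plan dose, organ masks, weekly fraction records.

    Deterministic in ``(spec.seed, patient_index)``.  The planning part of the
    stream is independent of ``with_fractions``, so planned anatomy is
    identical whether or not the fraction records are generated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, patient_index]))
    n_frac = int(rng.choice(spec.fraction_choices))
    rx = n_frac * spec.dose_per_fraction_gy
    coords = _world_coords(spec)
    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    centre = extent / 2.0
    r_target = rng.uniform(*spec.target_radius_range_mm)
    bath_frac = rng.uniform(*spec.bath_frac_range)
    r_bath = r_target + rng.uniform(*spec.bath_extra_radius_mm)
    d = np.linalg.norm(coords - centre, axis=-1)
    # conformal high-dose region plus the surrounding mid-dose bath
    high = expit((r_target - d) / spec.penumbra_mm)
    bath = bath_frac * expit((r_bath - d) / spec.bath_penumbra_mm)
    plan_values = rx * np.maximum(high, bath)
    plan = DoseGrid(plan_values, spec.spacing, (0.0, 0.0, 0.0))

    masks: dict[str, StructureMask] = {}
    for organ in spec.organs:
        radius = rng.uniform(*organ.radius_range_mm)
        target_mean = rng.normal(organ.dmean_mu_gy, organ.dmean_sd_gy)
        mask, _ = _place_organ(plan_values, coords, centre, organ, radius, target_mean)
        masks[organ.name] = StructureMask(mask, organ.name, spec.spacing, (0.0, 0.0, 0.0))

    fractions: list[FractionRecord] = []
    if with_fractions:
        base, extra = divmod(n_frac, spec.n_weeks)
        weights = [base + (1 if w < extra else 0) for w in range(spec.n_weeks)]
        for week, weight in enumerate(weights, start=1):
            if spec.dose_noise_sd > 0:
                noise = spec.dose_noise_sd * _smooth_unit_field(rng, spec.shape)
                dose_vals = np.clip(plan_values * (1.0 + noise), 0.0, None)
            else:
                dose_vals = plan_values.copy()
            if spec.displacement_sd_mm > 0:
                disp = np.stack(
                    [
                        spec.displacement_sd_mm * _smooth_unit_field(rng, spec.shape)
                        for _ in range(3)
                    ],
                    axis=-1,
                )
                dvf = DeformationField(disp, spec.spacing, (0.0, 0.0, 0.0))
            else:
                dvf = DeformationField.identity(spec.shape, spec.spacing)
            shift = (
                rng.normal(0.0, spec.rigid_shift_sd_mm, size=3)
                if spec.rigid_shift_sd_mm > 0
                else np.zeros(3)
            )
            fractions.append(
                FractionRecord(
                    index=week,
                    week=week,
                    dose=DoseGrid(dose_vals, spec.spacing, (0.0, 0.0, 0.0)),
                    dvf=dvf,
                    rigid_shift=tuple(shift),
                    n_fractions_represented=weight,
                )
            )
    return SyntheticPatient(
        index=patient_index,
        plan=plan,
        masks=masks,
        fractions=fractions,
        n_fractions=n_frac,
        prescription_gy=rx,
    )


def delivered_dose(patient: SyntheticPatient) -> DoseGrid:
    """Accumulated delivered dose of one patient's weekly fraction records."""
    return accumulate(
        patient.fractions, patient.plan, plan_total_fractions=patient.n_fractions
    )


def planned_dvh(patient: SyntheticPatient, organ: str, bin_width: float = 0.5) -> CumulativeDVH:
    return dvh_from_dose(patient.plan, patient.masks[organ], bin_width)


def delivered_dvh(patient: SyntheticPatient, organ: str, bin_width: float = 0.5) -> CumulativeDVH:
    return dvh_from_dose(delivered_dose(patient), patient.masks[organ], bin_width)


def sample_responses(
    ddvhs: list[DifferentialDVH],
    truth: SerialityParams,
    seed: int,
    *,
    symptom_id: str = "r1",
    scale_max: int = 4,
    patient_ids: list[str] | None = None,
) -> tuple[list[ResponderLabel], list[PCSIRecord]]:
    """Bernoulli 12-month responder labels from the NTCP ground truth.

    Returns labels plus a full PCSI record set (baseline, one on-treatment
    week, 12-month follow-up) constructed so that dichotomization reproduces
    the sampled labels exactly: responders go from level 1 to >= 3.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    if patient_ids is None:
        patient_ids = [f"p{i:04d}" for i in range(len(ddvhs))]
    labels: list[ResponderLabel] = []
    records: list[PCSIRecord] = []
    for pid, ddvh in zip(patient_ids, ddvhs):
        p = ntcp(ddvh, truth)
        y = bool(rng.random() < p)
        followup = int(rng.integers(3, scale_max + 1)) if y else int(rng.integers(1, 3))
        labels.append(
            ResponderLabel(patient_id=pid, symptom_id=symptom_id, responder=y, delta=followup - 1)
        )
        records.extend(
            [
                PCSIRecord(pid, symptom_id, BASELINE, 1, scale_max),
                PCSIRecord(pid, symptom_id, "week4", int(rng.integers(1, 3)), scale_max),
                PCSIRecord(pid, symptom_id, FOLLOWUP_12M, followup, scale_max),
            ]
        )
    return labels, records


def make_cohort(
    spec: CohortSpec,
    organ: str,
    *,
    n_patients: int | None = None,
    bin_width: float = 1.0,
    use_delivered: bool = False,
    label_seed: int | None = None,
) -> CohortDataset:
    """Labeled cohort for dose-response fitting, generated from ground truth.

    Planned (and optionally delivered) organ DVHs for ``n_patients``, with
    responder labels drawn from the organ's truth parameter set.
    """
    n = spec.n_patients if n_patients is None else n_patients
    organ_spec = spec.organ(organ)
    if organ_spec.truth is None:
        raise ValueError(f"organ {organ!r} has no truth parameters")
    planned: list[DifferentialDVH] = []
    delivered: list[DifferentialDVH] | None = [] if use_delivered else None
    for i in range(n):
        pat = generate_patient(spec, i, with_fractions=use_delivered)
        planned.append(differential_from_cumulative(planned_dvh(pat, organ, bin_width)))
        if delivered is not None:
            delivered.append(differential_from_cumulative(delivered_dvh(pat, organ, bin_width)))
    label_source = planned if delivered is None else delivered
    seed = spec.seed if label_seed is None else label_seed
    labels, _ = sample_responses(
        label_source, organ_spec.truth, seed, symptom_id=organ_spec.symptom_id
    )
    return CohortDataset(
        organ=organ,
        planned=planned,
        labels=np.array([l.responder for l in labels]),
        delivered=delivered,
        patient_ids=[l.patient_id for l in labels],
    )
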