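# Methods

## Dose-response model

The package implements the relative seriality NTCP model in the canonical
Poisson (Källman) form

    P(D) = 2^(−exp(e·γ·(1 − D/D50)))

This form satisfies the two defining properties of the parameterization —
P(D50) = 1/2 exactly, and a normalized gradient D·dP/dD at D50 equal to
(e·ln 2 / 2)·γ — and makes the biologically effective uniform dose (BEUD)
invertible in closed form:

    D̄̄(p) = D50 · [1 − (ln(−ln p) − ln ln 2) / (e·γ)]

**Equation-form caveat.** The literature also carries an alternative grouping
of the same sigmoid, P(D) = exp(−e^(e·γ − (D/D50)(e·γ − ln ln 2))). Both
forms agree exactly at D = D50 (and hence on every D50/BEUD identity this
package's reference quantities use) but diverge away from it. The canonical
form is used throughout. One practical consequence: under the canonical form
ln(−ln P) is linear in dose, so for a *parallel* organ (s → 0) the organ
response collapses to a function of the mean dose alone. The published
bladder cohort pairing of D_mean ≈ 45 Gy with NTCP ≈ 22% is consistent with
the alternative grouping rather than the canonical one; the synthetic
generator therefore targets the dose moments (which are unambiguous) and lets
NTCP follow from the adopted form (bladder cohort NTCP comes out ≈ 29–31%).

For a heterogeneous dose distribution with differential DVH {(Dᵢ, Δvᵢ)}:

    P_I = [1 − Πᵢ (1 − P(Dᵢ)^s)^Δvᵢ]^(1/s)

evaluated entirely in log space via y = −ln P = ln 2 · exp(e·γ(1 − D/D50)):
each factor is exp(Δvᵢ · ln(−expm1(−s·yᵢ))), which is accurate for s·y from
~10⁻³⁰⁰ up to overflow. Below s = 10⁻⁸ the analytic parallel limit
P_I = exp(−exp(Σ Δvᵢ ln yᵢ)) is used (the relative error of the direct
formula at s = 10⁻⁴ is below 10⁻⁴; the switchover avoids any loss of
precision for still smaller s). Bins at exactly 0 Gy are retained by
default — the Poisson sigmoid assigns unirradiated tissue a small positive
response probability, and for small s dropping such bins changes the organ
response; a flag exposes the dropping behavior for comparison.

Partial-organ uniform irradiation, P_I(D, V) = 1 − [1 − P(D)^s]^((V/V_ref)/s),
is implemented literally; note it matches a two-bin DVH through the
heterogeneous formula only when the unirradiated remainder's P(0) term is
included there.

BEUD is defined for NTCP strictly inside (0, 1) and additionally must lie at
or above the zero-dose response floor P(0); probabilities below the floor
have no non-negative uniform dose and raise an error.

## DVH conventions

Cumulative DVHs use "volume receiving ≥ dose", first edge at 0 Gy, fractions
relative to the whole segmented organ (V_ref). Default bin width is 0.1 Gy —
fine relative to the 1.8 Gy fraction dose; the binning is configurable
because metric values can shift by up to one bin width. D_xcc (dose to the
hottest x cm³) linearly interpolates the cumulative curve and, on plateaus,
takes the highest dose whose volume fraction still covers x — exact for
discrete voxel populations, and at most one bin width high for continuous
ones. D_mean is Σ Dᵢ Δvᵢ over bin centres (within one bin width of the true
voxel mean; tested against the direct voxel average). Grids use 0-based
indices with voxel-centre world coordinates x = origin + index · spacing.

## Dose accumulation

Fraction doses are mapped to the planning frame by an optional rigid shift
followed by a deformation vector field, both applied as pull-back trilinear
resampling: output(x) = input(x + displacement(x)), with outside-grid
positions contributing 0 Gy (conservative, and logged by the weight checks
rather than silently inflating dose). Pull-back rather than push-forward
splatting is used because it is deterministic and standard for dose warping.
Doses are physical accumulated doses; no linear-quadratic / EQD2 conversion
is applied (fraction doses are scaled and summed as physical dose).
Registration itself (the DIR algorithm) is out of scope: fields arrive as
inputs or come from the synthetic generator. Weekly imaging is handled by
explicit integer weights (n_fractions_represented); weights are never
inferred, and a sum that disagrees with the plan's fraction count triggers a
configurable warning or error. Organ restriction happens at DVH time, not
before summation — equivalent for DVH purposes and easier to verify.

## Outcome dichotomization

Symptom items are Likert 1–4 or 1–5, higher = worse. The responder rule is a
worsening of ≥ 2 levels at the follow-up timepoint (default 12 months)
relative to baseline; improvements and +1 shifts are non-responders. Both
the threshold and the timepoint are configuration values. Patients missing
either timepoint are excluded and reported separately, never imputed.

## Fitting

(D50, γ, s) are estimated by maximizing the Bernoulli log-likelihood of the
responder labels given per-patient NTCP values — binning-free, unlike least
squares on grouped incidence. s is optimized as log₁₀ s on [−6, 1] because
plausible organs span four orders of magnitude; D50 ∈ [20, 200] Gy,
γ ∈ [0.05, 10]. The likelihood is multimodal in s, so L-BFGS-B runs from a
deterministic 3×3×3 grid of starts over the bounds (plus the caller's
initial guess and optional jittered extras) and keeps the best optimum.
Probabilities are clamped to [10⁻¹², 1 − 10⁻¹²] inside the objective. A fit
ending on the D50 or γ bound is flagged as possible separation rather than
silently returned; s on a bound merely sets `at_bounds` (a parallel organ's
likelihood is genuinely flat in s below ~10⁻²). Confidence intervals use the
profile likelihood at the χ²(1) quantile — the provenance of the published
parameter ranges is not stated, so the method is labelled in the output.
Planned DVHs are fitted by default (matching how the parameter sets were
derived); a flag switches to delivered DVHs.

### Identifiability

On synthetic cohorts the rectum truth set (D50 inside the cohort's dose
range, steep γ) is recovered at n = 500 with a median |D50| error of ~4%,
consistent with its Cramér–Rao bound (SE ≈ 3.3 Gy). The bladder truth set is
intrinsically harder: D50 = 80.9 Gy lies *above* the whole cohort dose range
(organ mean doses ≤ ~70 Gy), so D50 acts as an extrapolated intercept. The
Cramér–Rao bound at the bladder truth on such a cohort is SE(D50) ≈ 14 Gy
(≈ 17%), i.e. an expected median |error| of ~11% at n = 500 even for an
ideal estimator — mirrored by the very wide published bladder range
(65.7–108.2 Gy at n = 141). The recovery test asserts a 5% median for both
organs; the bladder assertion fails for this statistical reason, with the
fitted optimum verified to beat the truth's likelihood on every replicate
(so the optimizer is not the cause). Fitted s for bladder-like cohorts is
essentially unidentified, again because a parallel organ's NTCP depends on
the DVH only through the mean dose.

## Evaluation statistics

AUC uses midrank tie handling, equal to the Mann–Whitney probability with
half credit for ties, and is verified against exhaustive pair counting. The
planned-vs-delivered comparison defaults to a *paired* t-test (plans and
delivered doses are matched per patient); a two-sample mode exists because
both test names appear in the source analyses, and the output always names
the mode used. Zero-variance paired differences are reported as degenerate
(p = 1 for literally identical vectors; p undefined for a constant nonzero
shift) instead of p = 0. No multiple-testing correction is applied; p-values
are raw and labelled as such.

## Synthetic cohorts

The generator reproduces the *statistical* structure the analysis needs, not
anatomy:

* **Plan dose**: a central spherical target (radius 10–14 mm, prescription
  40–44 fractions × 1.8 Gy) with a 4 mm sigmoid penumbra, surrounded by a
  mid-dose bath (45–60% of prescription, extending 8–16 mm beyond the target
  with an 8 mm falloff) that stands in for the dose spread of a multi-field
  IMRT plan. Grids are 32³ voxels at 3 mm — small enough for seconds-scale
  tests.
* **Organs**: prolate-ellipsoid surrogates (transverse radius 5–8 mm bladder
  / 5–7.5 mm rectum, elongation 1.8) aimed along ±y so they straddle the
  dose gradient; each patient's organ is offset by bisection until its mean
  plan dose matches a draw from the published cohort distribution (bladder
  44.9 ± 13.6 Gy, rectum 42.8 ± 7.3 Gy). Realized 46-patient cohort means
  sit within 2 SE of those targets across seeds; per-patient DVHs span
  near-zero to prescription dose, and the rectum cohort's NTCP distribution
  lands near the published 12.6 ± 5.9%.
* **Fractions**: weekly records (8 weeks, integer weights summing to the
  fraction count) perturb the plan with smooth Gaussian-filtered
  multiplicative dose noise (3% SD), smooth random displacement fields
  (2 mm RMS) and small rigid shifts (1 mm SD per axis) — organ-deformation
  surrogates with controllable magnitude, not biomechanics. Setting all
  scales to zero makes the accumulated delivered dose reproduce the plan
  bit-for-bit, which the tests exploit as a pipeline identity.
* **Outcomes**: responder labels are Bernoulli draws from the organ's truth
  NTCP; the accompanying questionnaire records are constructed so that
  dichotomization reproduces the labels exactly (responders move from level
  1 to ≥ 3).

All randomness flows from a single seed through per-patient substreams
derived from (seed, patient index), so one seed fixes every downstream
number and any single patient can be regenerated in isolation.

What passing tests therefore show: the pipeline's algebra (accumulation
conservation, DVH metrics, model limits, label plumbing, estimator
correctness) and parameter recovery under a *known-model, known-noise*
regime. What they do not show: robustness to real anatomical deformation,
registration error, delineation variability, or model misspecification —
none of which the surrogates emulate. Organ surrogates are a few cm³, so
absolute-volume metrics (D_1cc, D_10cc) have a different meaning than on
clinical organs and are reported as unavailable when the requested volume
exceeds the organ.

## Numerical choices

* DVH bin width 0.1 Gy default; fitting cohorts use 1 Gy bins (the
  likelihood is insensitive at that scale and the padded cohort matrices
  stay small).
* Recovery experiments use n = 500 patients and 20 replicates per organ —
  large enough for the rectum median error to sit well under its asserted
  bound, small enough for the whole suite to run in a few minutes.
* Trilinear out-of-grid reads are 0 Gy; interpolated dose is clipped at 0 to
  remove −10⁻¹⁶-scale rounding.
* Profile-interval search doubles an initial 5% step outward until the
  χ²(1) cutoff is crossed, then Brent root-finding on the profile; sides
  that hit a parameter bound first are reported at the bound and flagged.
* Ties in AUC: midranks. Degenerate t-tests: flagged, never p = 0.
* The fit flags rather than errors when the optimum touches a bound, except
  for class counts: fewer than 3 responders or 3 non-responders refuses to
  fit at all.

## I/O formats

Cumulative DVHs exchange as CSV (`dose_gy,volume_fraction` with organ label
and volume in comment headers). Volumes and 3-component vector fields are
NIfTI with axis-aligned affines. Questionnaire data is long-format CSV
(patient, symptom, timepoint, level, scale max). Fraction manifests are CSV
rows of dose/DVF paths, rigid shift components and integer weights.
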