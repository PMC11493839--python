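# Methods

## The model

Plasma quinidine kinetics in Thoroughbred horses are described by a
three-compartment mammillary model: a central compartment of volume `V1`
(L/kg) exchanging drug with two peripheral compartments (`V2`, `V3`) through
the distribution clearances `CL2` and `CL3` (L/kg/h), with elimination from
the central compartment at plasma clearance `CL`. Oral doses pass through a
gut compartment absorbed at the first-order rate `Kabs` (1/h) with
bioavailability `F`; intravenous doses are zero-order infusions (5 min by
default, matching how the drug is given clinically). Everything is
normalized per kilogram of body weight, so concentrations come out in mg/L,
identical to the μg/mL scale used for plasma quinidine.

The system is linear, so the package solves it in closed form. The
clearance/volume parameterization is converted to micro rate constants
(`k10 = CL/V1`, `k12 = CL2/V1`, `k21 = CL2/V2`, `k13 = CL3/V1`,
`k31 = CL3/V3`); the disposition exponents α > β > γ are the negated
eigenvalues of the mammillary rate matrix, obtained numerically from the
3×3 eigenproblem rather than from the explicit cubic (same roots, better
conditioning). Each dose contributes a sum of exponentials — the unit-bolus
response for IV boluses, its integral for zero-order infusions, and its
convolution with the gut flux for oral doses — and arbitrary schedules are
superposed by linearity. When `Kabs` falls within 1e-8 (relative) of a
disposition exponent the degenerate convolution term switches to its
L'Hôpital limit `c·t·exp(-λt)`, so profiles vary smoothly through the
coincidence. A peripheral compartment with zero distribution clearance is
decoupled and the system reduced (the one-compartment limit returns the
single exponent `k10`); genuinely repeated exponents of the coupled system
are reported as a `DegenerateDispositionError` rather than silently
mis-expanded.

Between-subject variability is log-normal: `θ_i = θ_tv · exp(η_i)` with
`η ~ N(0, Ω)`, and a log-variance ω² is reported as
`CV% = 100·sqrt(exp(ω²) − 1)`. Observations carry a combined residual
error, `y = f·(1+ε₁) + ε₂`, with route-specific proportional and additive
standard deviations. Sampled individual `F` is left untruncated (it can
marginally exceed 1, with probability ≈0.1% at the reported 33.1% CV); a
user can cap it, but the default keeps the stated exponential model intact.

## Bundled population estimates

`equipopk.io.load_table1()` returns the published bootstrap-median typical
values, BSV CV% per parameter and route-specific residual SDs: V1 0.63,
V2 0.59, V3 3.68 L/kg; CL 0.49, CL2 2.87, CL3 2.44 L/kg/h; Kabs 1.0 1/h;
F 0.364; BSV 40.5/37.8/28.5/25.6/74.9/47.3/94.3/33.1%; proportional
residual SD 0.0594 (IV) and 0.1571 (PO); additive SD 0.0338 and 0.0479.
The additive SDs are printed in the source with a "μg/L" unit label, but
their magnitude sits exactly at the assay's 0.03 μg/mL quantitation limit
and all concentrations in the analysis are in μg/mL; the package therefore
interprets them as μg/mL. This remains an open question of the source
table, and only affects the smallest concentrations.

### Reconstructed omega correlation

The source analysis used a full Ω matrix but published only its diagonal.
For the simulated regimens this matters: the concentration a horse settles
at under oral maintenance dosing is proportional to `F/CL`, so
`var(ln C) ≈ ω²_CL + ω²_F − 2ρ·ω_CL·ω_F`. Under independence
(ρ = 0) that variance is 0.167; the published 10/90 percentile band of the
45 mg/kg + 9 mg/kg q 2 h simulation (1.9–3.8 μg/mL) implies ≈0.073,
i.e. ρ(CL, F) ≈ +0.6 — physiologically plausible, since both CL and the
oral dose's systemic availability scale with hepatic extraction. The
bundled parameter file therefore carries `rho(CL,F) = 0.60` as a clearly
labelled *reconstruction calibrated to that published band*, applied only
when `load_table1(with_correlation=True)` is requested. As a check, the
same correlation reproduces the published band of the *other* regimen
(30/6.5: simulated 1.4/2.8 vs published 1.4/2.7) and the reported ~80%
probability of ending inside the 2.0–3.8 μg/mL window for the 45/9
regimen. Cohort medians are insensitive to the correlation, so all median
predictions use the diagonal specification.

## Dose design and Monte Carlo simulation

The loading dose fills the steady-state volume to the target,
`loading = target · Vss / F` with `Vss = V1+V2+V3`; the maintenance rate
replaces elimination, `rate = target · CL / F`. Doses are computed on the
quinidine base scale and converted with the salt factors 1.206 (sulfate
dihydrate) and 1.168 (hydrochloride monohydrate). Named regimens cover the
classical 22 mg/kg schedules (q 2 h ×4, q 6 h ×2), the 30/6.5 and 45/9
loading/maintenance schedules, and the 3-day escalation (15/3, 30/6.5,
40/9).

Monte Carlo cohorts sample individuals from the population model and
simulate noise-free individual curves (the measurement error says nothing
about exposure) on a 0.05-h grid — fine enough that percentile summaries
are free of discretization artifacts. Two end-of-day readouts are exposed:
the point concentration at a grid time (`CohortSimulation.at`), and the
concentration *attained* by that time (`attained_at`), the maximum over the
final dosing interval. The published "concentration at 24 h" values for
the loading/maintenance regimens correspond to the attained readout (the
day-end peak visible in the published figures): at the typical parameters
the attained values are 2.04 and 2.85 μg/mL for the 30/6.5 and 45/9
regimens versus published medians 2.0 and 2.8, while the literal 24-h
trough sits 0.2–0.3 μg/mL lower. Summaries include pointwise percentile
bands, the probability of target attainment against the 2.0–3.8 μg/mL
window, the fraction of subjects ever exceeding a safety threshold, and
time-in-window by piecewise-linear crossing interpolation.

## Synthetic studies

The generator emulates the study designs: a 6-horse IV/PO crossover
(4.28 mg/kg base IV over 5 min; 16.58 mg/kg base PO after a two-week
washout, represented as a 336-h gap in one record series) with the dense
sampling schedules; a 4-horse 20 mg/kg q 6 h ×2 oral arm; and a sparse
19-horse clinical cohort with doses uniform over 9.3–30.6 mg/kg sulfate at
4–6-h intervals and samples at 0.5–4 h. The IV "0 min" sample is placed at
the end of the infusion, with later offsets counted from there. Pre-dose
samples are generated as true zeros and then censored at the 0.03 μg/mL
quantitation limit; censored records are flagged and excluded from fitting,
and the below-quantitation fraction (over post-dose samples) is reported
with a warning at ≥5%, where exclusion-based handling starts to bias fits.

Clinical events are simulated as the first crossing of subject-specific
log-normal concentration thresholds (medians 2.0 μg/mL for conversion to
sinus rhythm, 3.8 μg/mL for adverse effects; configurable CV). This event
model is entirely synthetic — the source recorded real clinical events —
and exists so the window-derivation procedure has annotated data to work
on. A blood sample is emitted at each event time, mirroring clinical
practice. The window derivation pools quantifiable observations within a
lookback window (default 1 h) before each event and reports the median and
range per event class. Note the rising-phase bias this procedure inherits:
samples drawn shortly *before* a crossing lie below the threshold, so with
sparse sampling the derived "therapeutic concentration" underestimates the
crossing threshold; tests therefore verify recovery with sampling matched
to the lookback resolution.

What the generator does not emulate: inter-occasion variability,
absorption lag times, nasogastric dose loss, assay calibration drift, or
any pharmacodynamic link between concentration and conversion probability.
Passing tests show the estimation and summarization machinery is correct
under the stated model, not that the model captures every feature of real
clinical data.

## Estimation

The published estimates were produced with a proprietary commercial
expectation–maximization engine; this package implements a documented
open alternative whose adequacy is judged by parameter recovery, not
engine equivalence.

*Stage one* fits each subject by weighted least squares in log-parameter
space. Residual variance weights are evaluated at the observed
concentrations (`v_j = σ_prop²·y_j² + σ_add²`), which makes the per-subject
objective an exact WLS problem — convenient numerically, exactly equivalent
to ML with a fixed variance function, and the reason noise-free data are
recovered to optimizer precision. The search is bounded to ±3.5 log units
around the starting values (≈33-fold, beyond 4 SD of the widest reported
BSV) because the distribution-phase parameters (V2, CL2, CL3) are only
weakly identified from the 5–45-min early samples and unbounded fits can
diverge. `Kabs` and `F` are fixed at population values for IV-only
subjects. Three jittered starts guard against local minima.

*Stage two* (default, `method="its"`) is the iterative two-stage scheme:
each subject is refit as a MAP estimate under the current population prior,
typical values absorb the mean of the MAP etas, and the diagonal Ω is
updated EM-style as the mean of `η̂² + posterior variance`. Residual SDs
are re-estimated each sweep by pooled ML with the propagated posterior
prediction variance added to the squared residuals — without that
correction the MAP-overfit residuals collapse the proportional sigma. The
plain pooling path (`method="sts"`: log-domain means; sample variance minus
estimation variance, floored at zero with a warning) is retained; it is
what the covariate search consumes, since MAP shrinkage attenuates
covariate contrasts. The iteration count (default 8; the recovery exercise
uses 12) is enough for the updates to settle to <1% on the rich design.

Shrinkage is computed as `1 − var(η̂)/ω²` per parameter and flagged above
0.3, the conventional threshold past which a random effect is not robustly
estimable. The conditional log-likelihood at the individual estimates and
`BIC = −2LL + k·ln(N_obs)` are reported for bookkeeping. A Laplace
approximation to the marginal likelihood (MAP + Gauss–Newton Hessian per
subject) is available for model comparison and optional refinement of the
typical values; the default path does not depend on it.

The parameter-recovery exercise simulates 24 crossover horses at the
bundled truth with the bundled residual error and refits from scratch; it
is run at a fixed dataset seed. At this cohort size the sampling noise of
the cohort itself is material — the geometric mean of a parameter with 75%
BSV varies with ≈14% SD across cohorts of 24 — so recovery bands of ±15%
describe a single simulated study, not an across-seed guarantee.

*Bootstrap*: subjects are resampled with replacement and the population fit
repeated; the summary mirrors the published layout (median, precision CV%,
2.5/97.5 percentiles, BSV%), with failed replicates counted and excluded.

*Covariate search* operates on the stage-one subject-level log-parameter
estimates through a random-effects meta-regression: `log θ̂_i ~ N(Xβ, τ² +
v_i)` with `v_i` the per-subject estimation variance, profiled over τ² —
this downweights poorly identified individual fits instead of letting them
dominate. Continuous covariates enter as a power model centred at the
median; categorical ones as a fractional (exponential) shift. Stepwise
selection uses the published thresholds: add only if BIC improves by more
than 6.635, delete unless removal worsens it by more than 10.823 (the
χ²₁ critical values at p = 0.01 and 0.001). Constant or collinear
candidate columns are reported and skipped.

*Diagnostics*: conditional weighted residuals use the first-order
linearization around the empirical-Bayes etas (`V = GΩGᵀ + diag(v)`,
Cholesky whitening); at the generating model they are N(0,1) to within
Monte Carlo error. The visual predictive check simulates replicate
datasets under the fitted model with the study's exact design and compares
observed 10/50/90 percentile curves per route with the replicate bands.
With zero residual error the weighted residuals are undefined and reported
as such.

## Numerical conventions

Units are fixed package-wide: hours, mg/kg, L/kg, μg/mL. Doses are stored
as administered salt and converted to base once at simulation entry. All
randomness flows through seeded `numpy` generators; identical seeds give
bit-identical cohorts. Problem sizes in the test suite (5,000-subject
cohorts for regimen summaries, 24 subjects for recovery, 100 draws for the
ODE cross-check, 100–200 replicates for VPC bands) match the scales the
analysis itself reports, with smaller cohorts in unit-level property
checks.

## Known limitations

- Below-quantitation data are excluded (as in the source analysis), not
  modelled with a censored likelihood; heavy censoring would bias fits.
- Ω is estimated as diagonal; the CL–F off-diagonal is a calibrated
  reconstruction, not an estimate, and other correlations are unknown, so
  simulated extreme percentiles under the diagonal default are wider than
  the published bands.
- No covariate effects, inter-occasion variability, absorption lag or
  saturable elimination are modelled (none were retained or reported in the
  source analysis).
- The two-stage estimator requires per-subject identifiability; very sparse
  designs (the clinical 5-sample schedule) support only MAP-regularized
  individual estimates with high shrinkage.
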