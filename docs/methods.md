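# Methods

## Scientific setting

Rutin (quercetin-3-O-rutinoside) is a flavonoid glycoside whose oral
bioavailability is poor; in the gut it is hydrolysed and conjugated, and the
circulating species after oral dosing are quercetin conjugates
(quercetin-3-O-glucuronide, Q3OG, and quercetin-3-O-sulfate, Q3OS, assayed
together as quercetin after enzymatic deconjugation).  *Physalis peruviana*
calyx extract contains rutin (14.8 µg/mg) in a plant matrix that alters its
pharmacokinetics.  The package implements the population-pharmacokinetic
analysis of a rat study comparing pure rutin with the calyx extract:
10 groups of 5 rats, IV bolus (rutin measured) and oral gavage (quercetin
conjugates measured), with rich sampling to 12 h (IV) or 24 h (oral) and a
lower limit of quantification (LLOQ) of 100 ng/mL.

## Structural models

**IV**: two-compartment disposition with first-order elimination from the
central compartment,

    dX1/dt = k21·X2 − (k12 + k)·X1,      dX2/dt = k12·X1 − k21·X2,

with C = X1/V.  **Oral**: the same disposition fed by two first-order
absorption sites — a fraction F1 of the absorbable dose enters a first
depot (rate ka1) at t = 0, the remaining 1−F1 enters a second depot (rate
ka2) only after a delay Tlag2.  The delayed second site reproduces the
double-peak concentration profiles produced by enteric recirculation of
the conjugates.  The published description writes the second-site input
with an indicator function δ(t ≥ Tlag2) and does not spell out the depot
amounts; we implement the standard interpretation (two depot state
variables, the second charged at t = Tlag2), which matches the model
diagram.

Both systems are linear, so the simulators evaluate the exact
bi-/tri-exponential closed forms (macro rate constants α, β with
α+β = k12+k21+k, αβ = k21·k).  This is a deliberate deviation from a
design that called for stiff ODE integration: the closed forms are exact
and two orders of magnitude faster, which matters inside SAEM; the stiff
integrators (`simulate_iv_ode`, `simulate_oral_ode`, LSODA with
rtol 1e-11/atol 1e-13 and an integration restart at t = Tlag2) are kept as
the independent numerical cross-check and the tests require agreement to
1e-6 relative.  Near-coincident rate constants (removable singularities of
the partial-fraction form) are handled by a 1e-7 relative nudge.

**Units** are fixed package-wide: dose mg/kg, volume L/kg, rate constants
1/h, time h, concentration ng/mL (1 mg/L = 1000 ng/mL).  Extract doses
enter the model as rutin equivalents (extract dose × 0.0148); the matrix
acts only through covariate effects.  No molecular-weight conversion is
applied between rutin dose and quercetin concentrations — the oral volume
and clearance are apparent quantities, as in the source analysis.

## Population model

Individual parameters arise from

    h(P_i) = h(P_pop) + β_level + η_i,

where h is log, or logit for parameters bounded in (0,1) on their unit
scale (V in the IV model, where the population value 0.0646 L/kg lies well
inside (0,1); F1 in the oral model).  One categorical covariate axis per
route: IV `source` (RU reference, GEXT extract), oral `dose_group` (D100
reference; D75, D500, D750, D1000).  Random effects are multivariate
normal on the transformed scale; the IV model carries Ω for V and k with a
(V,k) correlation, the oral model Ω for ka1, ka2, F1 and V without
correlations (the fitted-model table is taken as authoritative over
equation listings that show η terms on Tlag2 and k).  Residual error is
"combined": sd(f) = a + b·f by default (`form="linear"`), with
sd = √(a² + (b·f)²) available as `form="quadratic"`; the published work
names the combined model without printing the formula, and the linear form
is the default in the estimation software family it used.

## Synthetic studies

`design.default_design()` reproduces the trial layout exactly, including
the oral 0.30 h sampling time as printed (possibly a typo for 0.5 h — kept
verbatim).  `simulate_study` draws η per rat, simulates the profile at the
scheduled times, adds combined residual noise, and emits values below the
LLOQ as flagged BLQ records (including pre-dose zeros) rather than
dropping them, so downstream censoring policies stay testable.  The
generator emulates the study design and the fitted stochastic model; it
does not emulate assay-level artefacts (deconjugation efficiency,
dilution errors, body-weight variation), so passing recovery tests show
estimator correctness under the declared model, not robustness to model
misspecification.

## Non-compartmental analysis

Linear trapezoidal AUC on the observed points; λz by log-linear least
squares over suffixes of the strictly post-Cmax positive points, choosing
the best adjusted r² with ties going to the longer suffix (at least 3
points); AUC0-∞ = AUC0-last + C_last/λz; AUMC tail
C_last·(t_last/λz + 1/λz²); MRT = AUMC/AUC; Cl = 1000·D/AUC0-∞ (apparent,
over F, after oral dosing); Vdz = Cl/λz; Vdss = Cl·MRT (IV only); Cmax/Tmax
as the global maximum so double peaks are handled naturally.  BLQ records
before the first quantifiable observation count as zero; embedded and
trailing BLQ records are excluded (both defaults configurable).  Relative
bioavailability is the dose-normalised AUC ratio, with the reference group
an explicit argument defaulting to the lowest-dose pure-compound group.

## Estimation

`PopPKModel.fit` estimates fixed effects, covariate β, Ω (SDs and declared
correlations) and the residual components by SAEM with several
reliability layers.  The problem is genuinely awkward: the oral model has
26 free quantities, a flip-flop ambiguity between ka1 and k, and a flat
likelihood ridge trading ka1 against F1, V and k.  The layers are:

1. **Deterministic starting candidates.**  Naive-pooled fits (all random
   effects removed; the pooled likelihood is exact, so these are fully
   reproducible) from a deterministic grid of starts: two assumed
   residual-error weightings and, for oral models, first-site absorption
   rates spanning 0.05–0.4 1/h (absorption half-lives ≈ 2–14 h).  The
   pooled fits hold k12, k21, a and b at their starting values so the
   weighting assumptions are not optimised away.  Distinct solutions are
   ranked by the Laplace marginal likelihood of the full mixed model and
   the best `multistart` become chain starts.
2. **SAEM chains.**  Burn-in with step size 1, Metropolis-Hastings
   component-wise random walks on η (proposal scales adapted toward 35%
   acceptance), exact GLS M-steps for the means/βs of random-effect
   parameters, moment updates for Ω with simulated-annealing floors
   (at most 5% shrinkage per burn-in iteration, preventing premature
   variance collapse), and a trust-limited quasi-Newton M-step (batched
   finite-difference gradients, per-iteration movement capped at 0.2 on
   the transformed scale) for the quantities without random effects and
   the residual components.  The smoothing phase uses γ_t = t^−0.65 with
   Robbins–Monro averaging of the numeric block.  Defaults: 300 burn-in
   and 200 smoothing iterations, 5 MH sweeps per iteration; the recovery
   experiments use 150/200 because the pooled pre-fit already supplies
   near-converged starts.
3. **Chain selection and refinement.**  Chains are ranked by the
   deterministic Laplace marginal likelihood.  The winner is refined by
   direct quasi-Newton maximisation of the importance-sampled marginal
   likelihood (frozen per-subject multivariate-t proposals centred on the
   Laplace mode, common random numbers; samples refreshed between
   rounds).
4. **Profile polish (oral only).**  Because the (ka1, F1, V, k) ridge is
   nearly flat, the final step scans fixed values of ka1_pop (coarse
   ±0.35 then fine ±0.1 on the log scale), re-optimises every other free
   quantity at each grid point — including the covariate βs, which must
   counter-shift to keep the non-reference groups fitted — and keeps the
   point with the best Laplace likelihood.  Laplace is used for these
   comparisons because its approximation error drifts slowly along the
   ridge, whereas a frozen importance-sampling surface systematically
   favours the neighbourhood of its own proposal centre.

The reported log-likelihood is importance-sampled (default 500 samples per
subject); AIC = −2·logLik + 2·(number of free quantities).  Standard
errors come from the empirical Fisher information (outer products of
per-subject score vectors, central finite differences of the per-subject
importance-sampled likelihood contributions) — positive semidefinite by
construction; directions with numerically no information (e.g. a fixed
k12 ≈ 0 toy) are excluded from the inversion and reported as missing
rather than polluting the other SEs through a pseudo-inverse.  Wald tests
are z = estimate/SE with two-sided normal p-values.  IWRES uses the
per-subject η posterior modes.

**BLQ in estimation**: the default drops BLQ records; a censored
(M3-style) likelihood that integrates the Gaussian tail below the LLOQ is
available via ``blq="censored"``.

**VPC**: `n_sim` replicate studies are simulated under the fitted model
and the design; 5th/50th/95th percentile bands are computed per group and
time from the *quantifiable* simulated concentrations (the LLOQ is applied
to the simulations exactly as to the data, so bands and observations
describe the same conditional distribution), plus the fraction of observed
quantifiable concentrations inside the 90% interval.

## What the recovery experiments show

Simulating the full 25-rat arms from the final published models and
refitting recovers the IV V_pop and k_pop comfortably within 20% across
seeds.  The oral problem is harder: the profile likelihood in ka1 is so
flat that the maximum-likelihood estimate itself can sit ~20% from the
generating value for some simulated datasets (the data genuinely do not
pin ka1 tighter at this design size), which is why the recovery check is
formulated as 4 of 5 replicates.  Tlag2 is always recovered within ~1%
— the second-peak onset is strongly identified.

## Numerical choices and degenerate inputs

* Transformed-scale parameters are clipped to ±30 before exponentiation so
  transient optimizer excursions cannot overflow.
* Ω SDs are floored at 0.01 (transformed scale) during estimation.
* With no random effects at all, `fit` reduces to deterministic maximum
  likelihood (batched-gradient L-BFGS) — the degenerate path used by the
  pooled pre-fits and by the error-model comparison tests.
* λz fits require ≥3 positive post-peak points; otherwise the subject's
  extrapolated quantities are reported as missing and flagged.
* Profiles with fewer than 3 quantifiable observations are rejected for
  NCA; >20% AUC extrapolation is flagged.

## Problem sizes used by the test suite

Unit tests run on toy designs (2–40 rats, effectively one-compartment
models) with short SAEM runs; the acceptance tests run the full 25-rat
arms with the recovery configuration above (pooled pre-fit candidates,
two SAEM chains of 150+200 iterations, refinement and profile polish) and
1000-replicate VPCs.  The error-model AIC comparison uses pooled
(no-random-effects) fits on 8-rat studies across 5 replicates.

## Known limitations

* The real study's data-dependent quantities (the printed AIC values,
  SE/RSE columns and group SDs) depend on the animal observations and are
  not reproducible from synthetic data; property-based substitutes stand
  in (AIC definition checks, SE plausibility, error-model ranking).
* Inter-occasion variability, continuous covariates and saturable
  elimination are out of scope.
* The Laplace/importance-sampling likelihood machinery assumes reasonably
  informative per-subject data (≥ a handful of quantifiable points); very
  sparse designs would need the likelihood integrated differently.
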