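# Methods

## Structural model

Oral linezolid kinetics in children is described by a one-compartment model
with first-order absorption and elimination. All parameters are apparent
(CL/F, V/F) with bioavailability fixed at 1: only oral data are modelled
and linezolid's oral bioavailability is essentially complete, so F is not
identifiable and is absorbed into the parameters. Typical values scale
allometrically with body weight relative to 70 kg with fixed exponents
0.75 (clearance) and 1.0 (volume) — the standard theory-based choice in
paediatrics, not estimated from data.

The absorption rate constant is parameterized as an additive offset above
the elimination rate, Ka = θ_Ka + CL/V, and the offset (not total Ka) is
estimated. This enforces Ka > CL/V by construction, excluding flip-flop
kinetics, in which absorption becomes rate-limiting and the absorption and
disposition parameters exchange roles; with sparse paediatric sampling the
two modes are otherwise easy to confuse.

Closed forms are used throughout: the Bateman equation after a single dose
and its steady-state accumulation sum within one dosing interval.
Steady state is computed analytically from the dataset's steady-state
flags rather than by simulating run-in doses — exactly equivalent for
linear PK, and a superposition test (30 explicitly summed doses, max
deviation < 1e-6 mg/L) pins the equivalence. When |Ka − k| underflows, the
analytic Ka→k limit (the t·k·e^(−kt) form and its steady-state analogue)
replaces the generic expression; the curve is never evaluated as 0/0.
Steady-state exposure uses the linear-PK identity AUC_0–24ss = daily
dose / CL; Cmax/Tmax come from bounded scalar maximization of the
closed-form curve on one interval (tolerance 1e-8 h) and Cmin is the
pre-dose trough.

## Random effects and residual error

Between-subject variability is lognormal on CL and V (diagonal; the final
model of the motivating analysis carried no η covariance, and none is
fitted by default). Residual error is combined,
y = f(1+ε_p) + ε_a, with variance v = σ²_prop f² + σ²_add.

Because measured concentrations are reported as non-negative, the
estimator can treat the residual distribution as a normal left-truncated
at zero: the per-observation deviance gains 2·log Φ(f/√v). This matters
only where predictions approach zero relative to the additive error
(pre-dose troughs in small children); elsewhere Φ ≈ 1 and the term
vanishes. It is on by default (`FitSettings.truncated_residuals`) and can
be disabled to recover the plain Gaussian likelihood. Without it, typical
volume estimates from once-daily designs with low troughs are biased
upward by roughly 10% under the default error magnitudes, because the
truncation inflates observed troughs.

Two optional variance components mirror structures evaluated and then
dropped in the motivating analysis: inter-occasion variability on CL
(occasion-level lognormal effects, generic per-subject Laplace over
2 + n_occasions dimensions) and "inter-cohort variability", implemented as
a cohort-specific inflation of ω²_CL. A genuinely shared cohort-level
random effect would break the per-subject factorization of the marginal
likelihood, and with every subject in exactly one cohort a per-subject
cohort effect is statistically indistinguishable from BSV, so variance
stratification is the testable rendering of the idea. Both default to off.

## Marginal likelihood

For subject i with penalized deviance

    q(η) = Σ_j [ log v_j + (y_j − f_j)²/v_j ] (+ truncation terms)
           + ηᵀΩ⁻¹η,

the objective contribution is the Laplace approximation with interaction,

    OFV_i = q(η̂) + n_i log 2π + log|Ω| + log det(∇²q(η̂)/2),

with η̂ the conditional mode. "With interaction" means the residual
variance v is a function of the subject's own prediction at η̂, so
proportional error interacts with the individual profile.

Numerics. The inner mode search is a damped Newton iteration vectorized
across subjects: gradients are exact to machine precision by complex-step
differentiation of the closed-form model; the curvature is the
Gauss–Newton (expected/Fisher) form, 2 f′f′ᵀ/v + v′v′ᵀ/v² plus 2Ω⁻¹,
which is positive definite by construction. Steps are trust-region capped
at 2 log-units with backtracking; rare stragglers fall back to a
per-subject Nelder–Mead refinement. The expected rather than observed
curvature is also used in the log-determinant when fitting
(`method="foce"`): where a subject's conditional surface is nearly flat,
the observed-curvature determinant is violently sensitive to the mode
location and makes the outer objective effectively non-smooth, while the
expected curvature keeps it differentiable. The observed-curvature value
(`method="laplace"`) remains available for objective evaluation and is
the value checked against adaptive Gauss–Hermite quadrature (17 nodes per
dimension) in the test suite, to within 0.5 OFV units on small instances.
The inner solve always restarts from η = 0: a warm start across calls
would make the objective depend on the evaluation path and corrupt outer
finite-difference gradients. Inner tolerances (gradient 1e-5, stall
detection at 1e-9 deviance change) locate modes far beyond the precision
the outer problem needs, since the objective error is second-order in the
mode error.

The outer problem optimizes log-transformed θs and variances (bounds
±12 log-units; covariate coefficients untransformed) with L-BFGS-B,
forward-difference step 1e-6. Initial values come from naive two-stage
heuristics (CL from dose over 24·mean concentration, V from dose over
Cmax, allometrically rescaled medians; variances at 0.1) unless supplied.
Standard errors come from the central-difference Hessian of the OFV at
the optimum (step 1e-3): Cov = 2·H⁻¹, delta method back to the natural
scale, RSE% = 100·SE/|estimate|; a singular Hessian marks RSEs
unavailable. With both ω² = 0 the objective reduces exactly to the
fixed-effects weighted least-squares −2 log likelihood.

Empirical Bayes estimates are the conditional modes at the final
estimates; a subject with no observations sits at the prior mode (0, 0).
Shrinkage toward zero grows as per-subject information falls, which the
suite checks monotonically.

## Covariate search

Stepwise covariate modelling tests multiplicative covariate–parameter
relationships (linear, power, exponential, categorical shift) on CL, V or
the Ka offset: forward inclusion adds the most significant candidate by
likelihood-ratio test (1 df) while p < 0.05, backward elimination then
removes effects whose deletion gives p > 0.01 (the 0.2/0.05 sensitivity
setting is a parameter). Ties break on smallest p, then largest OFV drop,
then candidate order — the convention is arbitrary and recorded in the
audit trail, which logs every tested candidate, ΔOFV, p and decision.
Continuous effects are centred at the dataset median; candidate fits that
fail are skipped and logged.

## Diagnostics

The visual predictive check simulates replicate datasets at the original
design (same subjects, doses, times, weights; fresh η and ε), pools
observations at the nominal sampling times — the designs are nominal-time,
so time-binning artifacts are avoided — and compares observed 5th/50th/95th
percentiles against the 2.5–97.5% envelope of the simulated percentiles.
The default 500 replicates match the motivating analysis. Simulated
replicates are not truncated at zero, so the lower band honestly reflects
the fitted error model rather than the reporting convention.

The exposure table computes per-subject EBE-based metrics at the actual
daily dose (sum of doses in a 24 h window of the assessed occasion) and
stratifies by age (<10 vs ≥10 years) and daily dose (<10, 10–<20,
≥20 mg/kg, half-open boundaries). AUC is model-based (dose/CL) by default;
the printed-table alternative of observed-profile integration is
deliberately not implemented, as the model-based quantity is the one the
downstream dose optimization uses.

## Dose optimization

Two hundred replicate cohorts (a parameter) of children with weights
drawn uniformly over the banded range are simulated with lognormal
clearance variability; each child receives their band's dose and the
daily-equivalent AUC is dose/CL (alternate-day doses halved, valid under
linear PK). The optimizer selects, per band, the increment-constrained
dose minimizing |log(median AUC / 110)|. The deviation is measured on the
log scale so halving and doubling the target are equally bad; the choice
is forced by the published quarter-tablet column, where the 5–<7 kg band
takes 150 mg on alternate days but 7–<10 kg takes 150 mg daily — a linear
deviation rule would push both to alternate-day dosing. Regimes: exact
(10 mg increments), 20 mg/mL suspension (20 mg = 1 mL increments, not
offered at ≥16 kg where volumes become impractical), 600 mg tablet
(150 mg quarter-tablet increments with the alternate-day fallback for the
smallest band only). The weight sampler is uniform — the least-assumptive
reading of "weights 5–56 kg" — and configurable.

A caveat the acceptance suite makes explicit: the published
formulation-independent doses for bands at and above 16 kg (220, 280,
400, 600 mg) sit systematically above any median-exposure-matching
solution under this model — the continuous optima are ~202, 258, 339 and
404 mg — with the >44 kg band's 600 mg evidently the adult-dose
convention rather than an optimizer output. Consequently, simulating the
published table over uniform 5–56 kg weights yields a pooled median AUC
near 127 mg·h/L, about 16% above the 110 target, and the optimizer
reproduces the published doses only for the lighter bands. The package
reports what the stated criterion computes rather than forcing agreement.

## Safety analyses

Event rates are events per 100 person-years with half-up presentation
rounding. Kaplan–Meier curves and the two-group log-rank test go through
lifelines; both are cross-checked against hand product-limit and risk-set
computations. The restricted-mean-survival-time comparison (used when
curves cross and proportional hazards fails) integrates each KM curve to
τ and tests the difference with the Greenwood-type variance
Σ [∫ₜ^τ S du]² d_i/(n_i(n_i−d_i)), computed in-package because no
installed library exposes the two-group RMST test; the no-censoring case
collapses to the exact mean of min(T, τ). Exposure comparisons use the
two-sided Wilcoxon rank-sum (exact for small untied samples). Group
splits follow the study: the cohort-median AUC_0–24ss of 107 mg·h/L and a
2 mg/L trough threshold. Censoring is at linezolid discontinuation or end
of follow-up; lower-grade events do not censor the grade-3/4 analysis.
Cmin–AUC correlation is Pearson on untransformed values by default,
Spearman behind a flag.

## Synthetic cohorts

The generator emulates the combined observational cohorts: 48 children by
default, ages uniform on 0.6–15.3 y, 31/48 sampled after a single dose,
9/48 multiple-dose children in the first cohort (sampling pre-dose, 1, 2,
4, 8 and 6-or-11 h, the 6/11 choice a fair coin since the allocation is
unstated), the rest in the second (pre-dose, 1, 4, 10 h). Routine dosing
is 10 mg/kg/dose, twice daily under 10 years and once daily from
10 years, capped at 600 mg/day. Weight comes from age through a smooth
monotone growth curve (median 4 + 2.2·age + 0.07·age² kg, 15% lognormal
noise, clipped to 4.5–60 kg) chosen so weights span ~5–56 kg over the age
range; covariate frequencies (sex, HIV, ethnicity, nasogastric route,
formulation by age) match the cohort tables at the marginal level only.
No joint covariate structure beyond weight-from-age is claimed, so
passing recovery tests demonstrate estimator correctness under the
study's design geometry, not robustness to real-world covariate
correlation, assay artifacts or adherence patterns.

Concentrations are drawn from the closed-form model with the combined
error; negative draws are resampled (making the realized residual
distribution the truncated normal the estimator models). The toxicity
generator draws event times from an exponential hazard
h = h₀·exp(s·(AUC−110)) with h₀ = 0.0018/day and s = 0.01 per mg·h/L —
calibrated so that at the target exposure roughly 60% of subjects have an
event within a median 17.7-month follow-up, matching the observed
any-grade event frequency — with grade-3/4 odds rising in AUC and
follow-up lognormal in months. Cohort, concentration and safety
generation use independent sub-streams of the seed.

## Problem sizes

The recovery experiments use 500-subject cohorts (about 2,000
observations), ten replicates for the recovery criterion, 200 replicate
cohorts for dose simulation and 500 replicates for the VPC — the sizes
the motivating analysis states or that give the estimator's sampling
error a comfortable margin against the tolerances being tested. A
500-subject fit takes roughly 20–40 s on one CPU.

## Known limitations

* No lag time, transit absorption, nonlinear elimination or
  autoinduction; the multiple-dose data of the motivating study showed no
  such trends, and the closed forms rely on linearity.
* No infusion records or multi-compartment disposition.
* The FOCE-flavoured objective (expected curvature in the determinant) is
  an approximation chosen for smoothness; its value differs from exact
  Laplace by fractions of an OFV unit per subject on sparse designs,
  which cancels in nested-model comparisons fitted the same way.
* The SCM explores only the four stated functional forms and does not
  search η covariance structures.
* Grades are inputs; no laboratory-value grading engine is included.
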