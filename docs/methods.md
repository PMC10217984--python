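# Methods

## Growth laws and inflection analytics

Three fixed-shape, three-parameter sigmoids are supported. With age *t*
in weeks (t = 0 is hatch, real-valued ages allowed) and trait value *Y*:

- logistic: Y = A / (1 + B e^(−kt))
- von Bertalanffy: Y = A (1 − B e^(−kt))³
- Gompertz: Y = A exp(−B e^(−kt))

A > 0 is the upper asymptote in trait units, B > 0 the dimensionless
adjustment parameter, k > 0 the instantaneous growth rate per week; the
parameter domain is enforced everywhere (each law degenerates otherwise).
The Gompertz form is the standard double exponential, consistent with its
inflection value A/e, and the Gompertz inflexion age ln(B)/k coincides
with the logistic formula — that is the standard result, not a typo.

Inflection analytics use the closed forms only (no numerical
differentiation in public results): inflection value w = A/2, 8A/27, A/e;
inflexion age ln(B)/k, ln(3B)/k, ln(B)/k; maximal weekly increment kw/2,
3kw/2, kw. Natural logarithms throughout. A negative inflexion age
(B < 1 for logistic/Gompertz, 3B < 1 for von Bertalanffy) is a legitimate
curve whose inflection precedes hatch; it is returned as-is with a
`before_origin` flag and a `UserWarning`, never raised as an error.

Two caveats on the von Bertalanffy law: its value at t = 0 is negative
when B > 1 (the cube of a negative number), and its curvature has a second
zero at t = ln(B)/k where the curve touches zero. Both lie outside the
observable domain for realistic fits (B < 1); tests of positivity and of
the single curvature sign change therefore restrict to t ≥ 0.

## Fitting

`GrowthCurveRegressor` estimates (A, B, k) by Levenberg–Marquardt least
squares (`scipy.optimize.least_squares`, method `"lm"`) on the raw
residuals with an analytic Jacobian. Positivity is enforced by optimising
over log(A, B, k); the Jacobian picks up the chain-rule factor
diag(A, B, k). Ordinary (unweighted) least squares is used — the data
grain is weekly means, and heteroscedasticity handling is out of scope.

Initialization: A₀ = 1.05 × max(y); (B₀, k₀) from an ordinary linear
regression on the model's linearisation — ln(A₀/y − 1), ln(−ln(y/A₀)) or
ln(1 − (y/A₀)^(1/3)) against t, each of which equals ln B − k t under the
respective law — skipping points where the transform is undefined. A
degenerate linearisation (fewer than two usable points, or a non-positive
slope as for a constant series) raises `InitializationError`; `fit` then
falls back to fixed starting values B = 10, k = 0.5.

Convergence: relative SSE decrease below 1e−12 (`ftol`) or relative
parameter step below 1e−10 (`xtol`), capped at 500 residual evaluations.
Non-convergence is reported on the result (`converged=False` plus the
solver message), never silently. R² = 1 − SSE/SST with SST about the
observed mean; negative values are allowed and reported. A series with
zero variance is rejected (R² undefined). At least 5 observations are
required for a 3-parameter fit.

Model selection follows the published practice: highest R², ties broken
by lower SSE, then by the fixed order logistic, Gompertz, von Bertalanffy.
Non-converged candidates are excluded with a warning; selection fails only
if every candidate failed. AIC/BIC and parameter standard errors are
deliberately out of scope.

Refitting the packaged Shitou/Wuzong weekly body-weight means reproduces
the published logistic parameters to roughly four significant figures,
which indicates those estimates were themselves obtained from weekly
means; the package still treats parameter-level agreement as
tolerance-based (0.25 weeks on the inflexion age) rather than exact, since
the original fitting software and data grain are not fully specified.

## Rate tables

Weekly absolute gain is the difference between consecutive observed
values; relative growth rate is 100 × gain / previous value (the
denominator choice is verified by the published rows: 220.72/194.60 =
113.42 %). The first observed week has no gain or rate — represented as
missing, not zero. Non-consecutive observations produce a gain over the
actual interval with the interval length recorded. Gains telescope to the
total growth exactly. Values are kept in full precision and rounded only
for display (2 decimals in CSV output). The growth-surge window is the
longest contiguous run of weeks whose gain and rate both clear the given
thresholds (ties to the earliest run).

One reproducibility note: published gain/rate rows were evidently computed
from unrounded means — e.g. the printed means give 1176.13 − 775.65 =
400.48 against a printed gain of 400.47, and a printed rate of 165.15 %
against a recomputed 165.13 %. Recomputations from printed means can
therefore differ by one unit in the last printed digit (±0.01 g on gains,
±0.02 percentage points on rates); the tests assert at exactly that
precision.

## Synthetic cohorts

`simulate_cohort` emulates the underlying measurement design: a cohort of
`n_birds` (default 40, the typical per-breed cohort size) measured at
fixed ages (default weeks 0–12), each bird's value Y(t)·exp(ε) with
ε ~ N(0, σ), σ = √ln(1 + cv²), so each observation has coefficient of
variation `cv` around the shared curve and stays positive. Weekly means
across birds form the series the fitter consumes. Identical configurations
are bit-identical (seeded `default_rng`); at zero noise the means equal
the curve exactly. Because no between-bird variance components were
published, the default noise levels (2–5 % CV in tests) are illustrative;
between-bird random effects (bird-specific A) are not simulated. The
generator reproduces the statistical structure the fitting assumes —
independent multiplicative noise around a true sigmoid — and not features
of real cohorts such as serial correlation within birds, mortality, or
model misspecification, so recovery results bound estimation error under
the model, not under field conditions.

Parameter-recovery experiments draw (A, B, k) log-uniformly over ranges
spanning the published trait fits (A from a few cm to several kg, k in
0.25–0.8 per week, B chosen per law so the inflection falls inside the
0–12-week window); with 40 birds at 2 % CV the median relative parameter
error is below 5 %, and noiseless data is recovered to 1e−6 relative.

## qPCR utility

Relative expression uses the comparative-Ct method: fold change =
2^−ΔΔCt with ΔCt = Ct_target − Ct_reference within a sample and ΔΔCt
taken against a calibrator sample. Technical replicates are averaged on
the Ct scale before differencing (the standard convention). Amplification
efficiency is fixed at 2 per cycle; efficiency-corrected models are out of
scope. Only formula-level properties are testable (identity at ΔΔCt = 0,
reciprocity under sign flip, monotonicity in target Ct) — no per-replicate
Ct data were published.

## Numerical test oracles and problem sizes

Gradients are checked against central finite differences (relative step
1e−6) at representative ages. Closed-form inflexion ages are checked
against the sign change of a fourth-order five-point finite-difference
second derivative (h = 0.01), localised by bisection to 1e−9; the stencil
keeps truncation and roundoff below the 1e−6-week tolerance. Fitted SSE is
checked against a dense 40³ brute-force grid on short series. The
recovery experiments use 100 replicate cohorts per law and the Monte-Carlo
inflexion-age check uses 200 cohorts of 40 birds — sizes chosen to keep
the whole suite under a minute while leaving the statistical assertions
comfortably away from their thresholds.

## Known limitations

- Fixed-shape three-parameter laws only; no Richards or multiphasic
  generalisations, and no mixed-effects or individual-bird modelling.
- Fits operate on weekly means; uncertainty in the means (SEs, cohort
  sizes per week) is not propagated.
- Model comparison is by R² alone, matching the published practice, and
  is not a substitute for information-criterion-based selection when
  models differ in effective flexibility.
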