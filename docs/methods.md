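# Methods

## Model family

Disease onset is modeled as a first-passage event of senescent-cell
abundance `X(t)` across an individual threshold.  `X` follows the
saturated-removal (SR) equation

    dX = (η t − β X/(κ + X)) dt + √(2ε) dW,     X(0) = 0,

integrated by Euler–Maruyama with `X` clamped to 0 after each step
(the simplest non-negativity-preserving scheme; a reflecting boundary
in the small-step limit).  The default step is `dt = 0.01` yr; the
test suite checks that sample means agree with a 10×-finer reference
within Monte-Carlo error.

The first-passage hazard across a threshold `Xc` is logistic in age,
`h(t) = A e^{at}/(1 + b e^{at})`, with threshold-dependent parameters
`ln A = A0 + A1 Xc`, `ln b = b0 + b1 Xc`, `a = a0 + a1 Xc` and
constants

    A0 = 4.14,  A1 = −1.01,  b0 = 2.24,  b1 = −0.81,
    a0 = −0.0186,  a1 = 0.0089,
    Ad = 2.22e−6,  bd = 9.774e−6,  ad = 0.132,  Xdeath = 17.

The log maps use natural logarithms; this is pinned by the consistency
check `hazard_params_from_threshold(17) ≈ (Ad, bd, ad)` (within the
rounding of the printed coefficients).  The onset survival has the
closed form `S(t) = ((1 + b e^{at})/(1 + b))^{−A/(ab)}`, the exact
integral of `h`; `a → 0` uses the limit `exp(−A t/(1+b))`.  Hazards
and cumulative hazards are evaluated in log space (`expit`,
`logaddexp`), so large `a·t` saturates at `A/b` instead of
overflowing.

Population incidence of the two-parameter model `(Xc, s)`:

    I(t) = s h S_s / (s S_s + (1−s) S_d).

The at-risk accounting behind this formula keeps susceptibles in the
pool until onset — their death before onset is neglected.  This is an
intrinsic approximation of the closed-form model, not a bug; the
cohort generator mirrors it (susceptible death ages are drawn
conditional on falling after onset) so that simulation and formula are
mutually consistent and the approximation is visible where it matters.
The death survival term uses `(Ad, bd, ad)`; the disease survival uses
the mapped `(A, b, a)` — the decomposition that also underlies the
threshold-distribution model.

The three-parameter model integrates `(Xc → h, S_s)` over a Gaussian
threshold distribution `N(X̄c, σ)` with 201 evenly spaced quadrature
nodes on ±5σ, truncated at `Xc > 0` with renormalized weights;
`σ = 0` returns the two-parameter expression identically, and the
node count is validated against a 10⁴-node Riemann sum (≤ 1e−4
relative error in the tested regime).

## Calibrated SR parameters

The human SR rates are not fixed a priori here; the shipped defaults
(`src/srinc/data/sr_params.yaml`)

    η = 0.602,  β = 65.6,  κ = 0.00586,  ε = 67.5

were obtained by matching simulated first-passage behaviour to the
closed-form hazard family: a differential-evolution global search
followed by Nelder–Mead polish (common random numbers make the
objective deterministic), minimizing (i) variance-stabilized error of
the crossing CDFs at thresholds 12–17 over ages 10–110, (ii) relative
error of the aggregated incidence of the canonical disease
(Xc = 14, s = 0.1) against the two-parameter formula, (iii) a
young-adult anchor `⟨X⟩ ≈ 1` over ages 10–30, and (iv) the
death-hazard exponential slope over ages 30–70 against `ad`.

The selected regime is *fully saturated removal*: `κ` is far below
physiological `X`, so removal runs at capacity `β` and crossings are
noise-driven excursions of the exponential upper tail of the `X`
distribution.  In this regime the hazard-slope relation
`a ≈ η Xc / ε` holds exactly in form (here `η/ε = 0.0089 = a1`).  A
profile over fixed `κ ∈ {0.3, 2.3}` shows the hazard family genuinely
selects this regime — parameter sets with `κ` of order 1, which would
be the natural reading of removal that saturates only gradually, fit
the printed hazard constants roughly an order of magnitude worse.

Validation of the defaults: crossing-CDF deviation < 0.09 per
threshold (n = 8000 paths), young-adult mean level 1.04, death-hazard
log slope 0.119/yr (binned 30–70; the analytic family measured the
same way gives 0.130 — the logistic hazard decelerates, so binned
slopes sit below `ad`), and cohort incidence at (14, 0.1) within 3
binomial SEs of the closed form in every informative 2-year bin at
n = 20,000.

`calibrate_sr_parameters` exposes the library form of this procedure
(Nelder–Mead on the variance-stabilized CDF loss with the young-level
anchor); the test suite demonstrates recovery of `η/ε` within ±20%
from self-generated targets.

## Synthetic cohorts

`simulate_cohort` draws susceptibility `Bernoulli(s)` and, for
susceptibles, a threshold (`Xc` or truncated-normal by rejection; the
mass below zero is negligible in the realistic ranges).  In
closed-form mode onset ages come from analytic inverse-CDF sampling of
`S_s`; in SDE mode onset and death are first crossings of the
individual threshold and of `Xdeath` on the *same* trajectory, so
onset (at `Xc ≤ 17`) always precedes death.  Aggregation uses 1-year
bins by default (bin centers as ages), with exact person-year
accounting: individuals leave the at-risk pool at onset or death, and
bins with zero person-years report missing, not zero.

What the generator emulates: threshold-mixture onset structure,
competing mortality from the same senescent process, binomial
sampling noise.  What it does not: enrollment churn, diagnostic
coding noise, cohort effects, secular trends, age heaping — so
passing round-trip tests demonstrates internal consistency of the
method, not robustness to real-record pathologies.

## Fitting

Weighted least squares on the linear incidence scale.  With counts,
weights are inverse squared 95% CI half-widths (normal approximation
to the Poisson rate; zero-count bins use the one-count resolution
limit) floored at 5% relative precision per point — an explicit
systematic-error floor; without counts, uniform.  The global stage is
a grid over `Xc ∈ [5, 17]` (to 25 when thresholds above `Xdeath` are
explicitly allowed, the dementia-like regime) step 0.5 and
`log10 s ∈ [−5, 0]` step 0.25 (σ ∈ [0, 5] step 0.5 for the 3p model),
followed by bounded trust-region refinement from the best five cells;
the fit is deterministic.  `R²` is always reported unweighted on the
linear scale; a flat input, which the mixture family cannot produce,
yields a converged fit with non-positive `R²` rather than an error.
Age-relatedness classes close on the left: slope ≥ 0.03/yr is mild,
≥ 0.07/yr strong.

## Treatment

Senescent cells are produced in two types: a fraction `f` of
production is drug-sensitive, the rest insensitive; both compartments
share the saturating removal computed on total `X`, and each carries
noise `√(2εf)`, `√(2ε(1−f))`, so the untreated sum is statistically
identical to the one-compartment process.  Each application multiplies
the sensitive compartment by `(1 − kill_fraction)`; the default
regimen kills it completely, since the per-application fraction behind
the reference scenario is not fixed anywhere and full removal is the
natural reading of an effective senolytic.  Treated and untreated arms
share noise paths (common random numbers), making per-individual
comparisons monotone and strongly variance-reduced.

The incidence-curve shift — reported in the literature without a
definition — is defined here as the mean horizontal displacement
obtained by inverse interpolation: each treated point in the window
(default ages 62–100, 2-year bins) is matched to the untreated age
with equal smoothed log-incidence on the untreated rising limb
(lowess, frac 0.3; smoothing can be disabled, in which case the metric
is translation-exact on noiseless shifted curves).

Under the calibrated noise-tail regime the monthly-from-60 scenario
with `f = 0.25` reproduces a ≈ 25-year shift and a ≈ 10-fold incidence
drop within a year, and the 2-month/40% regimen shifts ≈ 9 years.
Cumulative prevalence to age 90, however, falls by only ≈ 40%: the
treated hazard is suppressed by a factor `e^{−f·a·t}` but keeps
growing, so integrated onsets between 60 and 90 remain substantial.  A
reduction near 80% requires a more ballistic crossing regime that the
printed hazard constants exclude (see the κ profile above); with the
original, unpublished SR parameter values this tension might resolve.
This limit is intrinsic to calibrating from the hazard family alone
and is reported as measured.

## Tissue circuits

Progenitor/differentiated dynamics
`dS/dt = (p − q − r1)S`, `dD/dt = qS − r2 D`, with
`p = p_max·g_X(X)·∏(responses)` and `q = q0·∏(responses)`.  Each of
the four regulatory arrows (S→p, D→p, S→q, D→q) is absent, positive
(`u/(K+u)`) or negative (`K/(K+u)`); `K = 1` in population units of
the default steady state.  Senescent inhibition is
`g_X = 1/(1 + X/X_half)` with `X_half = 6`, so for the default rates
(`p_max = 20`, `q0 = r1 = r2 = 3` per year — frontline progenitors
turn over on week-to-month scales) the hard-collapse condition
`p_max·g_X(Xc) = q0 + r1` lands at `Xc = 14`, a typical disease
threshold.  Homeostasis of a topology = existence of a linearly
stable positive steady state (numerical root + Jacobian eigenvalues,
margin −1e−6) that re-converges after ±20% initial-condition
perturbation; the marginal no-feedback circuit is thereby excluded.
With the default forms 26 of the 81 topologies are homeostatic; the
exact count depends on the response forms and rates, which the
original supplementary analysis fixed differently (17 of 81) — the
robust statements, verified here, are that the homeostatic subset is
non-empty and that *no* topology survives `r1 > p_max`.  Collapse of
an individual is recorded when `D` falls below 10% of its baseline
steady state while the circuit is driven by that individual's SR
trajectory (co-integrated by Euler at `dt = 0.02`); for a slow
noiseless ramp the collapse age matches the quasi-static prediction
`D*(X) = 0.1·D*(0)`.  Collapse incidence is fitted with uniform
weights over ages ≤ 90, the range typical incidence tables cover.

## Numerical choices and edge cases

- Crossings are detected on the integration grid (first grid age with
  `X ≥ threshold`), biasing ages late by at most `dt`.
- `peak_age` scans a 0.1-year grid on [0, 110], ties to the youngest
  age, and warns when the curve is monotone (e.g. `s = 1`).
- Problem sizes: cohort checks use 10⁶ (closed form) / 2×10⁴ (SDE)
  individuals, treatment scenarios 2×10⁴ paired, collapse cohorts 10⁴
  — sizes at which Monte-Carlo error is a few percent per bin while a
  full analysis runs in well under a minute each on one core.
- Seeds: every stochastic operation takes one integer seed;
  per-individual streams derive from it deterministically, so all
  outputs are bit-reproducible.

## Known limitations

- The SR parameter values are calibrated, not measured; any parameter
  set reproducing the hazard family is admissible, and quantities that
  depend on more than the first-passage law (notably long-horizon
  treatment benefit) inherit that degeneracy.
- The closed-form incidence is an approximation to the SR
  first-passage process; at ages below ~50 (where rates are tiny) and
  above ~95 the two differ systematically by tens of percent in
  relative terms.
- Death and onset use a single shared `X`; organ-specific senescence,
  non-susceptible-threshold heterogeneity, and time-varying
  susceptibility are out of scope.
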