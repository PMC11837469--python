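# Methods

## Model overview and assumptions

`irmsim` is a deterministic quantitative-genetics model of insecticide
resistance in mosquito populations. Resistance to each deployed insecticide
is a polygenic trait — the polygenic resistance score (PRS) — assumed
normally distributed in the population with a fixed phenotypic standard
deviation σ. Only trait means evolve; phenotypic variance is held constant
across generations, which is the standard infinitesimal-model simplification
when selection episodes are brief relative to recombination. There is no
age structure, no population dynamics and no transmission model: the unit
of time is the mosquito generation and the state is a small vector of trait
means.

Selection is by truncation: if a fraction p of exposed mosquitoes is
expected to survive an insecticide, exactly the top-p fraction of the trait
distribution survives. The probabilistic alternative (survival as a smooth
function of individual score) is deliberately out of scope: truncation
yields closed forms that make the mechanism transparent.

### From score to survival

* **Bioassay survival** `K_B(z̄) = z̄/(z̄ + K)` with half-saturation K = 900
  PRS units (Hill coefficient 1). This calibration reproduces the standard
  score/survival table exactly: 0 → 0%, 100 → 10%, 225 → 20%, 900 → 50%,
  3600 → 80%, and 47 → 5% to the table's rounding (the exact inverse of 5%
  is 47.37). Both constants are configurable; nothing in the package
  assumes n = 1. Negative scores are legal state values (a susceptibility
  reserve) and map to zero survival.
* **Field survival** `p = clamp(1 − ω·(1 − (φ₁K_B + φ₂)), 0, 1)` with
  φ₁ = 0.48, φ₂ = 0.15. At efficacy ω = 1 this is the plain
  bioassay-to-field regression; at ω = 0 everything survives; ω > 1 models
  above-recommended doses and can drive susceptible survival to zero. The
  linear-in-ω form was chosen because it meets all three anchors: the ω = 1
  regression, certain survival at ω = 0, and an LD₁₀₀-exceeding dose at
  ω ≳ 1.18.
* Population-level survival is evaluated **at the mean score**, not
  integrated over the score distribution. The calibration table pairs mean
  scores with single survival values, which fixes this convention; it also
  keeps the truncation fraction consistent between the analytic engine and
  the cohort simulator.

### Selection differentials

With exposure x (females; males at m·x, default m = 1) and exposed-survival
p, the parental population is the mixture of unexposed mosquitoes
(weight 1 − x, unshifted) and truncation survivors (weight x·p, shifted by
σφ(z_p)/p where z_p is the upper-tail normal quantile). The monotherapy
differential is therefore

    S = x·σ·φ(z_p) / ((1 − x) + x·p).

For mixtures, exposed mosquitoes must survive both components; the two
truncations are treated as independent given the means (joint survival
p_i·p_j), so

    S_i = x·σ·p_j·φ(z_{p_i}) / ((1 − x) + x·p_i·p_j).

This is where the strategy trade-off lives: an effective partner (small
p_j) thins the selected survivors of trait i so the unexposed pool dilutes
them more — mutual protection — while at x = 1 there is no unexposed pool
and the partner is irrelevant. Cross resistance does **not** enter the
truncation geometry (no bivariate tail integral); it enters only the
response stage, below. This is logged as an approximation: with |α| = 0.3
and σ equal across traits the bivariate correction to the joint survival is
second-order.

### Response and cross resistance

Between generations, each trait mean moves by the sex-specific Breeder's
equation R = h²·(S_♀ + S_♂)/2·β plus the correlated response from selection
on the partner trait, R_i += α·√(h²_I·h²_J)·S̄_j·β (standard
correlated-response form with equal phenotypic SDs; S̄ is the sex-averaged
differential). Sex-averaging happens before the cross-resistance term.
Fitness-cost differentials (default 0) are subtracted from the raw
differentials per sex and deme every generation. β (default 1) is a
timescale calibration knob and multiplies both direct and correlated
responses.

### Degree of control

`control = x·(1 − joint exposed survival)` — the fraction of adult females
killed in one generation. It is reported per generation as a diagnostic
only; without a population-dynamics model, multi-generation control cannot
be interpreted, so strategy outcomes never use it.

## Decay profiles

Efficacy decays linearly per generation (rates are stated in efficacy units
per generation, i.e. absolute, not proportional; no exponential mode is
offered because no anchor exists for one):

    two-stage: ω(τ) = max(0, ω₀ − δ_b·min(τ, τ_b) − δ_r·max(0, τ − τ_b))

with base rate δ_b ∈ {0.005, 0.015, 0.025} (default 0.015), threshold
τ_b = 15 generations, rapid rate δ_r = 0.08, plus `constant` and `none`
modes. Boundary convention: the base rate applies **through** generation
τ_b, the rapid rate strictly after (±1-generation sensitivity is noted but
immaterial to any reported comparison). Reduced-dose mixtures are modelled
by lowering ω₀ to 0.75 or 0.5 with unchanged rates. Redeployment always
resets ω to ω₀ regardless of history. Note that at the default rates and a
30-generation redeployment interval, efficacy hits zero around generation
25 — the deployment interval deliberately outlives the insecticide.

## Single-generation grids

The monotherapy grid crosses efficacy 0–1.2 (step 0.1) × exposure 0.1–1.0
(step 0.1) × initial resistance {0, 5, 10, 20, 50, 80}% (780 cells); the
mixture grid additionally crosses the partner's efficacy and resistance
(60,840 cells). Heritability 0.2, β = 1, α = 0, no dispersal, no costs;
male exposure equals female. The outcome per cell is the one-generation
change in bioassay survival (percentage points) and the degree of control.
Cells with exposure 1 and joint survival 0 (e.g. susceptible population,
ω = 1.2) leave no parents: they are flagged `degenerate`, the change is
recorded as NaN and control as 1. Rows are emitted in lexicographic sweep
order so CSV output is byte-stable.

A shape caveat discovered while verifying the response surface: the
interior maximum of the response over efficacy ("the hump") requires the
efficacy range actually to push exposed survival past the optimum. At the
boundary ω = 1.2 the response is still rising whenever
z_p·((1 − x) + x·p) < x·φ(z_p); numerically this happens at 50% initial
resistance for x ≥ 0.8 and at 80% for x ≥ 0.3. The hump is therefore
asserted unconditionally only at ≤ 20% initial resistance, and as existence
(some exposure shows it) at 50/80%.

## Multi-generation strategy simulator

Two demes: a treated site holding coverage C = 0.7 of the population and
untreated refugia. Per generation, in order: (1) current efficacies from
the decay profiles at deployment age τ; (2) selection step in the treated
deme; (3) cost-only step in refugia; (4) dispersal — each deme mixes a
fraction θ = 0.2 with the coverage-weighted pooled population, which
conserves the global mean exactly; (5) τ increments, with a scheduled
refresh (τ → 0) every 30 generations.

Withdrawal/return thresholds (10%/8% bioassay survival) are evaluated every
generation on the **treated-deme** mean (monitoring happens where
deployment occurs; a `global` mode exists). Sequence: on withdrawal the
next available insecticide is deployed fresh the following generation;
withdrawn insecticides return below 8%; the strategy ends when nothing is
deployable. Mixture: both components co-deploy at ω₀ ∈ {1, 0.75, 0.5}; the
strategy ends outright when either component crosses 10% (no fallback to
the surviving component). Runs are capped at 500 generations = 50 years;
censored lifespans enter comparisons at the cap, with a censored flag
carried through. The sequence arm deploys insecticide *i* first (a
configurable convention; in the mismatched-resistance scenario *i* is the
one carrying pre-existing resistance).

Scenario sweeps cross δ_b per insecticide {0.005, 0.015, 0.025}²,
α ∈ {−0.3, 0, 0.3} and mixture ω₀ ∈ {1, 0.75, 0.5} (81 comparisons) plus a
no-decay companion set (9), for scenario 1 (defaults), scenario 2
(initial means 25 ≙ 2.7% and 0) and scenario 3 (h² = 0.15 vs 0.25). Each
scenario takes a few seconds single-threaded.

## Monte-Carlo cohort oracle

`simulate_cohort` draws per-trait scores from independent normals, assigns
exposure by Bernoulli(x), and applies truncation survival sequentially —
exactly the assumptions behind the closed forms, so the empirical
differentials must converge to them as 1/√N. The truncation threshold uses
the theoretical normal quantile by default so the check isolates the
dilution/averaging algebra from quantile-estimation noise; an
empirical-quantile mode provides the end-to-end variant. Standard errors
are batch means over independent blocks (default 50; the verification
sweeps use 100), which is exact here because blocks are i.i.d. Correlated
traits are not simulated; the oracle validates the independent-truncation
engine, not the cross-resistance approximation.

The verification sweep (20 random settings, N = 10⁶, fixed seeds) asserts
agreement within 3 standard errors per differential. With ~30 z-scores a
correct implementation still has roughly an 8% chance of one marginal
excursion beyond 3; the bound is kept as-is rather than inflated, and the
seeds are the package-wide conventional defaults.

## Numerical choices

* Tail intensity i(p) = φ(z_p)/p computed via `scipy.special.ndtri`
  (vectorised, ~µs per call — the strategy sweeps make ~10⁵ generation
  steps). Differentials are computed through φ(z_p) rather than p·i(p) to
  avoid 0·∞ at p → 0 and p → 1.
* Survival below 1e−10 is clamped before the intensity (configurable
  floor); survival exactly 0 with exposure < 1 short-circuits to S = 0,
  and with exposure = 1 raises a degenerate-extinction error.
* Exact zero survival/efficacy cells short-circuit so that "no insecticide"
  gives identically zero change, not 1e−15.

## What passing tests do and do not show

The cohort generator emulates the model's own statistical assumptions
(normal scores, Bernoulli exposure, deterministic truncation). Agreement
between engine and cohorts therefore validates the algebra, not the
biology: real bioassay survival is an estimate from finite samples, real
exposure is heterogeneous, variance is not fixed, and truncation is an
idealisation of dose–response mortality. Strategy-level conclusions are
sign-level and conditional on the default parameterisation (notably the
30-generation redeployment interval and the 10%/8% thresholds).

## Known limitations

No evolving variance or allele frequencies; no mosquito demography,
density dependence or transmission; cross resistance only through the
correlated response; two insecticides and two strategies (sequence,
mixture) only; decay parameters are taken as given, not fitted to
durability data.
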