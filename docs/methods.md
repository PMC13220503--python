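# Methods

This note records the modelling choices, defaults and known limitations of
the pipeline, in the order the data flow through it.

## Synthetic evidence

The generator stands in for the trial publications an appraisal would
digitize. Its reference scenario is a two-arm, first-line-style trial in
metastatic colorectal cancer: Weibull event times with a common shape of
1.3 so that arms and endpoints are exactly proportional-hazards ordered,
comparator medians of about 20 months (OS) and 9 months (PFS), an OS hazard
ratio of 0.80 and PFS hazard ratio of 0.66 for the intervention, n = 400
per arm, 3 years of administrative follow-up and exponential dropout at
0.05/year. Cohort (age 60, 40% female), utilities (0.77 progression-free,
0.68 progressed), state costs (£133/£273 per month), terminal-care cost
(£6,265), administration/monitoring costs (£819–£1,527 per month) and fixed
treatment durations (5 and 4 months) are the published, non-confidential
appraisal inputs; tender prices, the vial menu, adverse-event inputs and
the body-metric distributions are synthetic stand-ins for confidential or
unpublished values.

Endpoints are coupled comonotonically: one uniform draw per subject is
pushed through both inverse survival functions, which guarantees per-subject
PFS ≤ OS whenever the marginals are ordered; the marginals are checked on a
grid and a crossing is rejected. Censoring (dropout draw and administrative
cutoff) is shared per subject. All simulation is inverse-transform from a
seeded generator, so identical seeds reproduce identical datasets
bit-for-bit. An improper Gompertz survival (negative shape) maps its
plateau mass to +∞ event times, which administrative censoring absorbs.

What the generator does *not* emulate: real digitization error from pixel
reading (optional uniform jitter is available but off by default),
non-proportional or crossing hazards in the reference scenario (crossing
marginals can be simulated per arm, just not through the coupled path),
informative censoring, and any attempt to mimic a specific published
trial's curves. Passing tests therefore demonstrate the machinery is
correct under known ground truth, not that any real trial is reproduced.

## Digitization and reconstruction

`digitize` samples the Kaplan–Meier estimate at a regular grid (default
spanning follow-up), so survival values at grid times are exact and drop
locations are preserved to grid resolution; numbers at risk are reported at
a configurable interval (6 months in the analyses here). The risk-table
convention is that n(t) counts subjects with observed time strictly greater
than t — the post-event count — and the reconstruction shares it.

`reconstruct_ipd` implements the interval algorithm: initial censoring
guesses per risk interval from the survival ratio, censorings spread evenly,
event counts from rounded product-limit drops, iteration until the implied
number at risk matches the next table entry, and a final calibration of the
last interval's censorings to the reported total event count when present
(both code paths exist because publications do not always report totals).
Noisy, non-monotone coordinates are repaired by a running minimum before
reconstruction. A risk table that is arithmetically impossible (more at
risk than subjects remaining, beyond a small rounding tolerance of
max(2, 5% of the interval's cohort)) raises an error naming the interval;
shortfalls inside the tolerance keep the closest achievable allocation.

**Round-trip fidelity measure.** The sup-norm between two step functions
over *all* times is dominated by phase spikes — an original KM drop
mid-cell versus the digitized drop at the next grid position — which no
reconstruction can remove; at a 60-point grid these spikes sit near 0.025
for a 300-subject arm regardless of algorithm quality, while the
reconstruction-level error is ≈0.002. The package therefore quotes
round-trip fidelity at the digitization grid times for coarse grids, and
the genuine all-time sup-norm (≤0.02) for fine grids (200 points), where
time quantization no longer dominates.

## Parametric fitting

All seven families maximize the right-censored log-likelihood
Σ_events ln f(t) + Σ_censored ln S(t) on a transformed scale (log for
strictly positive parameters, identity for the Gompertz shape, log-normal
location, and generalized-gamma μ and Q). The exponential rate has the
closed form events/person-time and is computed exactly. The others use
L-BFGS-B from method-of-moments starts plus three fixed perturbations,
then a Nelder–Mead polish — a fully deterministic recipe, so fits are
reproducible to the bit. The generalized gamma uses the log-time (μ, σ, Q)
parameterization with regularized incomplete-gamma survival evaluation
(Q→0 handled as the log-normal limit; Q < 0 supported); the Gompertz shape
may go negative, giving an improper plateau exp(b/a) that the finite model
horizon truncates. The covariance is the inverse observed information from
central finite differences, projected to the nearest positive semidefinite
matrix; it feeds the PSA on the same transformed scale. Fits were
cross-checked against independent implementations (lifelines in the test
suite; flexsurv during development) and agree in log-likelihood to ~1e-3.

**Recovery tolerances.** At n = 1000 with 25% administrative censoring the
observed information bounds single-dataset precision: the generalized-gamma
Q carries a standard error near 0.15, so no single fit can be guaranteed
within 10% of a realistic Q. Parameter-recovery checks therefore test the
mean estimate over ten seeded replicates against a 10% band — a bias and
consistency check, which is what recovery at fixed n can meaningfully
assert. Model-selection behaviour (the generating Weibull or its
generalized-gamma superset ranking first by AIC) is checked on complete
data, where the tail information separates Weibull from the gamma family;
under heavy administrative censoring those two families are statistically
near-equivalent at mCRC-like shapes and selection between them is close to
a coin flip — an inherent feature of censored evidence, not of the fitter.

Hazard shapes are classified on a dense grid by tolerance-guarded
sign-counting of finite differences into constant, increasing, decreasing,
unimodal and bathtub-like. The selection policy codifies the appraisal
practice: base case = best AIC among families whose shape matches the
clinically asserted trend (configurable, default increasing), the same
family enforced across arms via summed AIC; sensitivity = the converged
family with the largest absolute survival difference from the base case at
the horizon.

## Partitioned survival engine

Default cycle length one week (7/365.25 years) and horizon 40 years, by
which the 60-year-old cohort reaches age 100; with weekly cycles the
half-cycle correction (trapezoidal occupancy, discounting at cycle
midpoints with 1/(1+r)^t) leaves the engine within 0.5% of adaptive
quadrature, and halving the cycle moves discounted life-years by <0.2%.
Discount rates default to 3.5%/year for both costs and QALYs. PFS above OS
— possible with independently fitted or digitized curves — is clipped to
OS with a warning count rather than an error. Treatment exposure comes
either from a time-on-treatment KM curve (capped at PF occupancy) or from a
fixed mean duration: full exposure of the PF cohort until the mean
duration, zero after, which reproduces mean exposure while respecting
survival — one defensible reading, since the interaction of a fixed mean
with early deaths is not uniquely defined. No general-population mortality
floor is applied by default. The age decrement is a multiplicative index
from configurable quadratic utility-norm coefficients, normalized to 1 at
baseline age. Adverse-event disutilities and costs apply once on model
entry. Everything downstream is linear in utilities and unit costs, which
the tests exploit as exact scaling identities.

## Costing

Vial counting minimizes *cost*, not waste (the payer's objective; the two
differ when price per mg is non-monotone in vial size), by exact
enumeration with branch-and-bound over whole-vial combinations covering
the required dose; with vial sharing the cost is the required mg at the
cheapest per-mg rate, which never exceeds the whole-vial cost. The
body-metric expectation uses a deterministic 199-quantile grid per sex
(log-normal weight and BSA), keeping the deterministic base case exactly
reproducible. Tender prices are summarized by the market-share-weighted
mean (base case) or the weighted median — the smallest price whose
cumulative share reaches 0.5 — and enter as a scale factor on the vial
menu relative to its first-listed (reference) vial price.

## Economics

ICER and iNMB follow their definitions exactly, with dominance tags when
signs differ and an undefined tag when ΔQ = 0 with nonzero ΔC (iNMB is
still reported). The severity modifier classifies the QALY shortfall of
standard care against a life-table general population (annual product-sum
with mid-year survival, age/sex utility norm and half-year discounting):
weights 1.2 at proportional ≥ 0.85 or absolute ≥ 12 QALYs, 1.7 at ≥ 0.95 or
≥ 18 — configurable thresholds, since appraisal practice names the weights
but not always the cut-offs. The QALY credit for excluded subsequent
treatment lines is added to standard-care QALYs *only* inside the
shortfall computation, never to the ICER's increments: adding it to the
comparison itself would double-count post-progression QALYs, and the
credit exists precisely to avoid granting an inappropriately high severity
weight. The relative-ICER transfer (inferred second-line ICER =
second-line anchor × ratio of first-line ICERs) requires finite positive
ICERs and refuses dominance tags.

The PSA draws survival parameters multivariate-normally on the transformed
scale from each fit's covariance (nearest-PSD repaired when needed),
utilities from method-of-moments Beta and cost multipliers from unit-mean
Gamma distributions with standard errors defaulting to 10% of the mean
(the appraisal literature rarely publishes dispersion inputs); degenerate
(zero-variance) settings reproduce the deterministic result exactly, and
with 500–1000 draws the probabilistic means sit within a few percent of
the deterministic increments, reflecting the model's near-linearity. The
CEAC grid runs £0–£50,000 in £1,000 steps. Prices are held fixed in the
PSA by default (config-flagged), as tender prices are administrative
rather than sampled quantities.

## Problem sizes and limitations

The shipped analyses use n = 400 per arm, 60–200 point digitization grids,
10 recovery replicates per family, 50 selection replicates, and 500–1000
PSA draws — sizes at which every stochastic check holds with margin while
the full pipeline completes in well under a minute. Known limitations: no
spline-based or cure extrapolations (the menu is fixed at seven families);
no sequential treatment-line modelling (excluded by design, with the
shortfall credit as the compensating mechanism); the severity thresholds
and the subsequent-QALY credit are configuration inputs, not derived
quantities; and the synthetic tender prices make the absolute ICERs
illustrative — the health increments, not the money, are the quantities a
confidential-price appraisal can publish, which the redacted reporting
mode mirrors.
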