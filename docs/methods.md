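# Methods

## Models

All three structural models describe the viability fraction of a cell
population 24 h after exposure to a dose `d` (µM) of drug through the
logistic form `V(d) = V_max / (1 + exp(m (d − c)))`. The LD50 `c` is
the dose of half-maximal viability; the slope `m` (1/µM) is the
reciprocal of the spread σ of the underlying unimodal lethal-dose
distribution; `V_max ∈ (0, 1]` normalises for drug-independent death.
The models are nested:

* *single static*: one `(c, m)` shared by every assay group — the null
  hypothesis that sensitivity does not change across groups;
* *single dynamic*: an independent `(c, m)` per group, equivalent to
  fitting each group's dose-response curve separately;
* *two population*: a weighted sum of a sensitive and a resistant
  logistic state, `(c_s, m_s)` and `(c_r, m_r)` shared across groups,
  with only the sensitive fraction `f_s ∈ [0, 1]` varying per group.
  The states are given the canonical labelling `c_s < c_r` so the model
  is identified up to that ordering.

Assumptions: a well-mixed population, additive measurement error on
viability, and within each state a homogeneous logistic dose response.
The two-population model makes no mechanistic claim about *how* cells
reach each state (growth, death, or state transitions).

## V_max

`V_max` is a fixed normalisation, never a fitted parameter; the free
parameter counts (2, 2 per group, 4 + 1 per group) exclude it. By
default it is estimated as the mean viability of the dose-0 records,
which in a real assay are untreated wells. A caveat for purely
synthetic data: a logistic with `m·c ≈ 2` is only ~88% saturated at
zero dose, so the dose-0 sample mean then underestimates the generative
`V_max`; the parameter-recovery experiments therefore pass the
generative value to the fit explicitly, which every fitting function
supports.

## Fitting

Each fit minimises the sum of squared viability residuals with bounded
trust-region least squares (`scipy.optimize.least_squares`, `trf`;
cost tolerance 1e-10, parameter tolerance 1e-8). Bounds: LD50s in
(0, 2·max dose], slopes in (0, 10], fractions in [0, 1] — fraction
estimates at 0 or 1 are genuine bound solutions, not post-hoc clipping.
Ten starting points are used: a data-driven heuristic (LD50 at the dose
whose mean viability is nearest `V_max/2`, slope `4/dose-range`,
fractions 0.5) plus Latin-hypercube draws over the box with a fixed
sampler seed, making fits deterministic and independent of record
order. The two-population fit is one joint minimisation; the ordering
`c_s < c_r` is enforced by the reparameterisation `c_r = c_s + δ`,
`δ > 0`, which removes label switching without constraints. When the
fitted separation δ falls below 2 µM the result carries an
unidentifiable-mixture warning: two coincident states fit the data as a
single sigmoid and the fractions are arbitrary. The per-group fits of
the single dynamic model include the pooled static solution among their
starts, so its pooled rss can never exceed the static rss. A dataset
with no dose effect at all (flat per-dose means) is reported as
non-converged rather than fitted.

## Model selection and uncertainty

Models are compared by the Gaussian least-squares AIC,
`n ln(rss/n) + 2k`, lower is better; the small-sample AICc is
available behind a flag but is not the default, and only the AIC
*ordering* is meaningful — absolute values depend on the likelihood
convention. MSE (`rss/n`) is reported alongside. Non-converged fits
are excluded from winner selection with a warning.

Confidence intervals are percentile intervals from a case bootstrap
with 500 resampled datasets by default. Records are resampled with
replacement *within* each (group, dose) cell, preserving the balanced
assay design; the resampling unit is a deliberate convention, as is the
percentile (rather than BCa) interval. Each surrogate dataset is refit
warm-started from the original solution. If more than 10% of refits
fail, the summary is flagged unreliable.

## Synthetic assays

The generator emulates the assay structure: a 12-dose doxorubicin
panel (0–144 µM), groups that are either weeks after a drug pulse or
known sensitive/resistant mixtures (ratios 1:0, 3:1, 1:1, 1:3, 0:1,
i.e. resistant fractions 0–1), and 4 replicates per (group, dose) cell
by default (a typical plate layout; configurable). Noise is zero-mean
Gaussian with a per-dose standard deviation, truncated to [0, 1] —
the simplest noise matching a per-dose spread profile; the default
flat sd of 0.05 is a typical replicate spread for viability assays.
The per-dose profile can instead be estimated from data as the
df-weighted pooled within-(group, dose) standard deviation, with
singleton doses interpolated from neighbours. All randomness derives
from one root seed with per-(group, dose) substreams, so datasets are
bit-reproducible.

What the generator does *not* emulate: plate, batch or day effects;
correlated errors between doses on one plate; counting error that
scales with cell number; cell–cell interactions between mixed lines.
Passing recovery tests on this synthetic data therefore demonstrates
the estimator's correctness and its statistical identifiability under
idealised independent noise, not robustness to structured experimental
artefacts.

Reference generative values (`resistmix.reference`) are the published
point estimates for the MCF-7 / MCF-7-ADR doxorubicin system:
sensitive/resistant LD50s 22.4 / 79.7 µM with slopes 0.060 / 0.028
1/µM; untreated wild-type 37.0 µM at slope 0.055; the pure resistant
line 187.5 µM at slope 0.034 (assayed on a panel extended to 400 µM,
since its LD50 exceeds the standard panel). The default weekly
sensitive-fraction trajectory dips to 0.40 in weeks 2–3 and recovers to
0.95 by week 8, mimicking a transient resistance peak after a pulse.

## Population dynamics

Weekly bulk counts give per-capita growth rates
`ln(N_1/N_0)/Δt` (1/day) per interval, with t-intervals across
replicates. Projecting the first week's count through the rates gives
total cell numbers; multiplying by the fitted resistant fraction splits
them into resistant and sensitive counts (`N_res + N_sens = N_total`
bit-exactly by construction). The "compounded" interval on a
subpopulation count is the interval-arithmetic product of the
total-count interval and the fraction interval — a convention chosen
for transparency, with a uniform Monte-Carlo propagation available
behind `method="montecarlo"`; both treat the two uncertainty sources
as independent.

## Validation and identifiability

For known mixtures, the joint fit is run with groups = mixture
compositions and judged by the coefficient of determination between
estimated and measured resistant fractions, with residuals taken about
the line of unity (`R² = 1 − Σ(est−meas)²/Σ(meas−mean)²`); the
regression convention (squared correlation) is available behind a
flag. The identifiability study simulates `n_sim = 100` datasets of 5
mixtures by default, refits each, and reports per-parameter estimate
distributions, central 95% bands with truth-coverage flags, and
pairwise Welch t-tests between the mixture-fraction estimate
distributions (no multiple-testing correction by default, Bonferroni
behind a flag). As the two state LD50s approach each other the
fraction distributions widen and the pairwise tests lose significance
— mixture resolution degrades continuously with state separation.

## Problem sizes and numerical conventions

The test suite runs its stochastic property checks at reduced sizes
chosen to keep the default run inside a few minutes while retaining
power: AIC-selection frequencies over 100 simulated datasets per
scenario, bootstrap coverage over 200 repetitions of a single-curve
assay with the default 500 bootstrap resamples, identifiability bands
at 30 simulations. Recovery experiments average 25 noise realisations.
Degenerate inputs are handled explicitly: zero rss yields −inf AIC
with a degenerate warning; zero-variance distributions short-circuit
the t-test (p = 1 on equal means); truth values lying exactly on a
parameter bound are compared to identifiability bands with a 1e-9
numerical tolerance.

## Known limitations

* Exactly two states: with a 12-dose panel there is little power to
  resolve more, and no >2-state model is offered.
* Unweighted least squares; dose-dependent error variance is modelled
  in simulation but not exploited in fitting.
* The bootstrap treats (group, dose) cells as the exchangeable unit;
  plate-level correlation would invalidate its intervals.
* Interval compounding assumes independence of fraction and
  growth-rate uncertainty.
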