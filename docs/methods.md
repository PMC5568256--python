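# Methods

## Model and assumptions

Each trial j contributes a pair of independent binomial counts
X_cj ~ Binom(n_cj, p_c), X_tj ~ Binom(n_tj, p_t). The failure probability of
each arm carries a beta law; conjugacy makes every posterior
Beta(α + events, β + non-events). The cumulative meta-analysis chains these
updates in publication order (ties on the order key keep file order, then
break lexicographically on trial id — any deterministic rule gives the same
final posterior, since updating is a sum of counts).

Assumptions worth stating explicitly:

- **Arms are independent within a trial.** No within-trial correlation
  between the two arms is modelled (correlated alternatives such as the
  Sarmanov bivariate beta exist but are out of scope).
- **Common parameters across trials.** The conjugate chain treats every
  trial as sampling the same two failure probabilities, i.e. a fixed-effects
  reading. Between-trial heterogeneity is *not* absorbed by the Bayesian
  model; the DerSimonian–Laird comparator is provided precisely to check how
  much that matters on a given dataset (on the packaged example: τ² = 0.005,
  I² = 43%, yet the pooled RD of −0.020 sits within 0.015 of the Bayesian
  mean RD).
- **Default priors are uniform** Beta(1, 1) per arm; any proper beta prior
  can be supplied.

## Probability statements

Exceedance probabilities Pr(p_c − p_t > δ) are computed two ways:

- **Quadrature (default, deterministic).** Pr = ∫ f_t(p) S_c(p + δ) dp on a
  fixed 400-node Gauss–Legendre rule mapped to the effective support of the
  treated posterior (the 1e−14 to 1 − 1e−14 quantile range, intersected with
  the admissible region). Concentrating nodes on the support keeps relative
  accuracy high even for probabilities of order 1e−4, far below what Monte
  Carlo resolves at ordinary draw counts.
- **Monte Carlo (seeded).** Independent draws from the two betas; requires
  ≥ 1e5 draws, default 1e6, default seed 42. Used as a cross-check and in
  the credible-interval quantiles.

Sign conventions: exceedance statements use control − treated (positive δ =
treatment benefit); *reported* risk differences use treated − control, so
negative values favour the experimental arm. The risk-difference mean is
closed-form (difference of beta means); its equal-tailed credible interval
comes from Monte Carlo quantiles of the difference of posterior draws.

Arm credible intervals are equal-tailed beta quantiles by default — they are
reproducible without optimization and match how such intervals are usually
quoted. A highest-posterior-density interval is available behind a flag
(`posterior_summary(..., hpd=True)`), computed by minimizing interval width
over the lower tail split.

## Predictive probabilities

The predictive layer evaluates Pr(X_c/n_c − X_t/n_t ≥ δ) for a future sample,
where each future count is beta-binomial under the current posterior.

- **Enumeration (default, exact).** The double sum is rearranged so each
  treated count needs one survival-function evaluation of the control
  beta-binomial; permitted up to (n_c+1)(n_t+1) ≤ 1e7 cells.
- **Monte Carlo (seeded).** Rates first, then counts, following the
  hierarchy; default 1e6 replicates.

Two deliberate conventions:

- **"At least δ" is `≥`, not `>`.** Observed rates are discrete, so ties at
  exactly δ carry positive probability and the choice is material (for a
  40/40 sample from uniform priors, `≥ 0.05` gives 780/1681 ≈ 0.464 while
  `> 0.05` gives 0.401). `≥` is the reading validated against the worked
  example.
- **Cumulative-size future samples in the table.** In the cumulative table,
  state k predicts a new sample as large as the cumulative enrolment through
  trial k. This is the convention that reproduces the worked example's
  predictive columns (exact values 0.055 / 0.083 / 0.111 at states 5/12/13
  against quoted 5.4% / 8.6% / 11.2%, which were themselves MCMC estimates).
  Any explicit future size is available through `predictive_prob` with a
  `FutureSampleSpec`. The first-state value is the one place the quoted
  figures (48.5%, elsewhere 45%, themselves mutually inconsistent) are not
  reproduced by any size/tie convention we tested — the exact value is
  53.6% — so it is documented rather than targeted.

As the future sample grows, observed rates concentrate at the latent rates
and the predictive probability converges to the posterior probability
Pr(p_c − p_t > δ); this limit is property-tested.

## Design tools

**Evidence-shift grid.** For each design cell (n per arm, assumed treated
rate p_t*): draw p_c from the current control posterior, simulate fictive
counts Binom(n, p_c) and Binom(n, p_t*), fold them into both posteriors, and
evaluate the updated Pr(p_c − p_t > δ) by the vectorised quadrature. The
cell reports (a) the fraction of simulations whose updated probability
exceeds a decision threshold (default 0.8 — a conventional "80% chance of
demonstrating the effect" bar) and (b) the mean updated probability, so
either reading of "shifts the evidence" is available. Defaults: δ = 0.05,
2000 simulations per cell, seed 42. Treated counts are drawn from the fixed
assumed rate p_t*, not from a re-centred posterior: the grid answers "what
if the true treated rate were p_t*", which is the design question.

**Average-coverage sample size.** The smallest per-arm n such that, averaging
over new-trial data simulated from the current posterior predictive, the
posterior mass of the risk difference within a length-L interval centred at
the updated posterior mean is at least the target (defaults L = 0.05, target
0.95). The interval is centred at the mean rather than being an HPD interval
— deterministic, and consistent with the equal-tailed reporting elsewhere.
The search bisects on n, treating the Monte Carlo coverage curve as monotone
(more data always tightens the posterior; noise at the crossing is the one
caveat, so each candidate n is evaluated with a seed derived from (seed, n)
and reruns are reproducible). Coverage uses the same quadrature kernel
vectorised over simulations. No published value exists for this quantity, so
it is validated by properties (monotonicity in n and in L, seed stability).

## Frequentist comparator

DerSimonian–Laird random-effects pooling on the risk-difference scale:
per-trial RD = p̂_t − p̂_c with variance p̂(1−p̂)/n summed over arms,
moment estimator τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), pooled estimate by
1/(v + τ²) weights, Wald 95% CI, Q p-value from χ²(k−1), I² = max(0,
100(Q − df)/Q). Zero-event policy: an arm with no failures gets 0.5 added to
events and non-events (n grows by 1); trials with zero failures in *both*
arms are excluded; at least two eligible trials are required. The
implementation is checked against values computed independently with R's
metafor on identical corrected counts. Heterogeneity is conventionally
tested at the 0.1 level.

## Synthetic generator

`SyntheticConfig` draws one pair of binomial counts per configured size pair
from true rates (default homogeneous). Heterogeneity, when requested, is
injected on the logit scale — per-trial rates expit(logit(p) + N(0, τ²)) — so
τ = 0 recovers exactly the world the conjugate model assumes, and τ > 0
produces over-dispersion a random-effects comparator should detect. What the
generator does *not* emulate: publication bias, time trends in control risk,
within-trial arm correlation, or outcome misclassification. Passing
calibration tests on synthetic sequences therefore demonstrates correctness
of the machinery under the model's own assumptions, not robustness of the
model on real literatures.

## Numerical choices and degenerate inputs

- Quadrature order 400 (fixed); support truncation at beta quantiles 1e−14.
- Float ties in the predictive count cutoff are guarded with a 1e−9 slack
  before the ceiling, so exact rational thresholds (e.g. δ·n integer) land on
  the `≥` side.
- `update(prior, 0, 0)` is the identity; n = 0 cells in the design grid leave
  the posterior untouched (used as a no-update identity check).
- Probabilities are clipped to [0, 1] after quadrature to absorb rounding at
  the 1e−16 level.
- Validation is strict and early: counts outside [0, n], non-positive arm
  sizes, duplicate trial ids, unsorted cumulation input, empty design grids
  and oversize enumeration requests all raise with context.

## Test-scale choices

Simulation sizes in the test suite (e.g. 1e6 Monte Carlo draws for
agreement checks, 2000 simulations per design cell, 100–150 for coverage
searches, 50–100 replicate sequences for calibration) were chosen so that
3-standard-error bands are decisive for the properties being checked while
the whole suite stays fast enough to run routinely.

## Known limitations

- The fixed-effects Bayesian chain ignores between-trial heterogeneity; on
  heterogeneous literatures the posterior will be overconfident. Check the
  DL comparator's τ² and I² before trusting narrow credible intervals.
- The binomial-normal log-odds GLMM sometimes used as a random-effects
  sensitivity model is not implemented; the DL risk-difference pooling is.
- Funnel data are produced as (effect, size) pairs; no plotting and no
  small-study-effect test is included.
- MCMC-derived published values carry their own simulation error; exact
  recomputations here can differ from quoted figures by a few tenths of a
  percentage point.
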