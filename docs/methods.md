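# Methods

## Models

### Progesterone mixture (reproductive-state clustering)

Female blubber progesterone is modelled on the natural-log scale as a
two-component normal mixture,

    log y_i ~ (1 − w_B)·N(m_A, s_A²) + w_B·N(m_B, s_B²),

so each component is log-normal on the concentration scale and
`exp(m_A)`, `exp(m_B)` are geometric cluster means in ng g⁻¹. The
number of components is fixed at two: the model's purpose is to test a
specific bimodal hypothesis (low-progesterone resting/lactating females
versus high-progesterone luteal/pregnant females), not to select a
component count. Default priors are vague: `m_A, m_B ~ N(0, 10²)`,
`s ~ Half-Normal(5)` and `w_B ~ Uniform(0, 1)`, all overridable.

Label switching is resolved by per-draw relabelling to `m_A < m_B`
(means, spreads and weight swap together). This is exact for
label-invariant quantities and simpler than ordered priors.

The sampler targets the marginal likelihood (indicators summed out);
per-animal indicators `z_i` are then drawn from their exact conditional
— the responsibilities — for each retained parameter draw. Cluster
*occurrence* is the per-draw fraction of indicators in each cluster.
Note its posterior concentrates on the composition of the *sampled*
animals; the mixing weight `w_B` is the population-level quantity and
both are reported.

`cluster_source_probability(v)` averages the responsibility of a
hypothetical concentration `v` over the posterior, tracing the
probability curve that separates the clusters across the observed
range.

### Testosterone location model

Male testosterone uses a simple log-normal location model
`log y_i ~ N(mu, sigma²)` with the same vague priors; the headline
summary is `exp(mu)`, the geometric mean concentration.

### Seasonal model

Log testosterone follows a 365-day cosine,

    log y_i ~ N(alpha + A·cos(2π(d_i − phi)/365), sigma²),

with `alpha, A ~ N(0, 10²)`, `sigma ~ Half-Normal(5)` and the phase
`phi` uniform on the circle [0, 365). The period is fixed at 365 days;
leap days are ignored (far below the data's resolution).

**Sign/phase identifiability.** `(A, phi)` and `(−A, phi + 182.5)`
trace the same curve. Rather than constraining `phi` to a half cycle —
which would pin the sign of `A` to an arbitrary calendar half and make
"positive amplitude" meaningless — chains start at the harmonic
least-squares solution, which always has `A ≥ 0` with `phi` at the
apparent peak. When a true seasonal signal exists the posterior is
unimodal there (chains cannot cross `A = 0` through the likelihood
barrier), so the fraction of retained draws with `A > 0` reads as the
posterior certainty of a seasonal cycle and reaches 1 for strong
signals. Without a signal the likelihood barrier vanishes, the sign
mixes freely, and the same statistic sits near 0.5. The derived
per-draw peak day, `phi` for positive-amplitude draws and
`phi + 182.5` otherwise, always covers the full year; its summaries are
circular (draws unwrapped around the circular mean before taking
quantiles).

**Winter replication.** Records with day-of-year in the winter window
(default days 1–90, January–March, matching the study's described
winter sampling; configurable because "winter" is not a calendar-fixed
interval) are duplicated at `day + 365` and flagged `replicated=True`
before fitting. Since the model is 365-periodic this equals doubling
the winter records' likelihood weight — asserted as a test by comparing
against a weighted fit. Replication anchors both ends of the fitted
cycle when field effort leaves seasonal gaps.

**Bayesian R².** Per retained draw,
`BR² = Var_d(fitted log-mean) / (Var_d(fitted log-mean) + sigma²)`,
with the variance taken over the fitted records' days (weighted when
weights are in play). This is the standard fitted-over-total variance
construction and is bounded in [0, 1].

**Prediction bands.** Bands are pointwise 75% and 95% quantiles of the
per-draw *mean* curve `exp(alpha + A·cos(·))` — uncertainty of the
seasonal trend, not posterior-predictive intervals for individual
animals, which would be much wider at these residual spreads.

### Assay QC and validation

* Duplicate CV: `100·sd/mean` (sample sd, ddof 1); rerun above 10%.
* Working range 50–3200 pg mL⁻¹, bounds inclusive (the permissive
  reading; only exact-boundary values are affected), applied to the
  mean replicate concentration.
* Recovery efficiency: mean of per-spike percent recoveries, with
  their CV.
* Accuracy: Bayesian linear regression of measured on added mass
  (priors as above); slope CIs excluding 1 flag over-/under-estimation.
  BR² uses the same per-draw construction as the seasonal model.
* Parallelism: both curves fitted as lines in response versus
  log-concentration; parallel when the 95% CI of the slope difference
  contains 0. The linearised-response choice replaces what is usually
  an eyeball judgement; cross-reactivity percentages are documentation
  only.

## Sampler and diagnostics

Adaptive random-walk Metropolis, one coordinate at a time, with
proposal scales adapted toward ~44% acceptance only during the
discarded burn-in prefix; the retained chain is a valid Markov chain
for the target. Positive parameters are sampled on the log scale and
the mixing weight on the logit scale, with Jacobians in the posterior.
A floor of `log sigma > −30` keeps degenerate (noiseless) fits finite
without affecting any realistic posterior. Correctness is verified
against conjugate closed forms (normal mean, Beta–Bernoulli) and a
dense grid posterior for a small mixture.

Retained-draw bookkeeping: `floor(n_iterations·(1 − burn_in)/thin)` per
chain, realised by keeping the last `retained·thin` states subsampled
every `thin`; with the reference configuration (3 chains × 1,000,000
iterations, 10% burn-in, thin 20) this retains exactly 135,000 draws.
The desk-scale default (3 × 20,000, 10%, thin 5; 32,400 retained) keeps
every fit in seconds while leaving Monte-Carlo error far below the
posterior spreads of interest; all sizes are user-configurable.

Diagnostics are delegated to `arviz`: split-chain R̂
(`method="split"`, floored at 1, constant chains 1 by convention) and
autocorrelation ESS (`method="mean"`, capped at the retained count so
antithetic chains cannot report more than 100%). Summary quantiles are
order statistics (no interpolation), so they commute exactly with
monotone transforms such as `exp`; the SD column of exponentiated
summaries is the sd of the exponentiated draws (its geometric analogue
`exp(sd of log draws)` is available from the raw draws).

## Synthetic data

Generators invert each model with seeded `numpy` PCG64 streams; they
are pure functions of their parameter objects. Defaults encode the
emulated study: 38 female progesterone samples with cluster geometric
means 1.56 / 27.12 ng g⁻¹ and cluster-A weight 0.61; 45 male
testosterone samples with peak day 227 (mid August) and sampling days
uniform on [30, 300] to mimic the field-effort gap; spike-recovery
slope 0.83. Within-cluster log-sds (0.55, 0.85) and the seasonal
amplitude (1.0 log-unit) are plausibility choices — the emulated study
reports posterior summaries of cluster centers, not within-cluster
spreads or the amplitude — fixed once; the sds are chosen so cluster
overlap is confined to the tails.

What the generators do **not** emulate: repeat biopsies of the same
individual (every synthetic record is an independent animal; the models
likewise treat records as independent), inter-annual effects, regional
structure, assay censoring at the working-range limits, and
inter-individual baseline variability in the seasonal model. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the stated model, not robustness to those real-data
features.

## Numerical and design notes

* Dates are ISO-8601; day-of-year from the proleptic Gregorian
  calendar. Leap-day records keep day 60; the seasonal model always
  uses period 365.
* Concentrations are ng g⁻¹ at the record level; pg mL⁻¹ only inside
  plate data. Converting between them needs extract volume and blubber
  mass and is left to the caller.
* Mixture fits refuse fewer than 4 observations or all-identical data;
  the seasonal fit refuses fewer than 5 records or a single distinct
  day (phase unidentifiable).
* The pipeline derives per-stage seeds from the root seed via
  `numpy.random.SeedSequence(root, spawn_key=(stage_index,))`, so
  stages rerun standalone bit-identically.
* Test and acceptance runs use desk-scale problem sizes (n = 84–500
  records, 50-seed calibration loops at 2 × 5,000 iterations); these
  are the package's own default study conditions, with the
  reference-scale chain layout available as `REFERENCE_SCALE`.

## Known limitations

* Random-walk Metropolis mixes slowly for strongly correlated
  posteriors; the models here are low-dimensional and well-conditioned,
  but Neff% can sit well below 100 (the mixture's high-cluster mean
  typically retains ~30–70% efficiency).
* No random effects for repeat-sampled individuals; the seasonal model
  attributes all residual spread to `sigma`.
* Cluster labels carry no biological interpretation by themselves; the
  package reports clusters and membership probabilities only.
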