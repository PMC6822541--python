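# finhorm

Bayesian analysis of reproductive steroid hormones measured in whale
blubber biopsies.

Free-ranging baleen whales cannot be examined directly, so reproductive
state is inferred from steroid hormone concentrations in small blubber
biopsies quantified by enzyme immunoassay (EIA). `finhorm` implements
the full statistical pipeline for such a study — built around the case
of a resident fin whale population whose breeding seasonality was
inferred from blubber progesterone (females) and testosterone (males):

* **Assay QC and validation** — duplicate coefficient-of-variation
  rerun rule (CV > 10%), the 50–3200 pg mL⁻¹ working range,
  spike-recovery efficiency, a Bayesian accuracy regression
  (measured vs added mass; slope ≈ 1 means no matrix interference) and
  a parallelism test of pooled serial dilutions against the standard
  curve.
* **Reproductive-state clustering** — a two-component Bayesian normal
  mixture on log progesterone,
  `log y_i ~ (1−w_B)·N(m_A, s_A) + w_B·N(m_B, s_B)` with the
  identifiability constraint `m_A < m_B`, giving posterior cluster
  centers `μ_A = exp(m_A)`, `μ_B = exp(m_B)` (geometric means, ng g⁻¹),
  per-animal membership probabilities and the posterior cluster
  occurrence among sampled females.
* **Breeding seasonality** — a sinusoidal day-of-year model of log
  testosterone, `log y_i ~ N(α + A·cos(2π(d_i − φ)/365), σ)`, fitted
  after *winter replication* (winter records duplicated at day + 365 to
  anchor both ends of the annual cycle), reporting the posterior
  probability of a positive amplitude, the peak day, Bayesian R²
  (`BR² = Var(fit)/(Var(fit)+σ²)` per draw) and 75%/95% credible bands
  of the mean seasonal curve.
* **MCMC engine** — an adaptive random-walk Metropolis sampler with
  burn-in, thinning, split-chain R̂ and effective-sample-size
  diagnostics, and Table-style posterior summaries
  (Mean, SD, 2.5/25/50/75/97.5%, R̂, Neff%).
* **Synthetic data** — seeded generators that invert each model, so the
  whole pipeline is testable end to end without the (unpublished) field
  data.

## Worked example

Simulate a study-sized dataset and run the two analysis stages:

```sh
finhorm simulate --preset all --seed 1 --outdir fixtures
finhorm cluster fixtures/mixture.csv --outdir cluster_out --iters 12000 --thin 4 --seed 3
finhorm seasonal fixtures/seasonal.csv --outdir seasonal_out --iters 12000 --thin 4 --seed 7
```

The `cluster` command prints the posterior cluster occurrence among the
38 simulated females:

```json
{
  "fraction_A_mean": 0.6371734892787525,
  "fraction_A_ci95": [0.5, 0.6842105263157895],
  "fraction_B_mean": 0.36282651072124755,
  "fraction_B_ci95": [0.3157894736842105, 0.5]
}
```

about 64% of females in the low-progesterone cluster A (resting or
lactating) and 36% in the high cluster B (luteal phase / pregnant).
`cluster_out/cluster_means.csv` holds the cluster centers; in this run
the posterior median of μ_A was 1.48 ng g⁻¹ (95% CI 1.25–1.78) and of
μ_B 20.1 ng g⁻¹ (8.1–33.4), covering the generating geometric means of
1.56 and 27.12 ng g⁻¹.

The `seasonal` command prints:

```json
{
  "p_positive_amplitude": 1.0,
  "br2_mean": 0.6241376749284057,
  "br2_ci95": [0.4654241242934572, 0.7390125878070475],
  "peak_day_of_mean_curve": 224.0
}
```

i.e. the model is certain the 45 simulated males have a seasonal
testosterone cycle (every retained draw has a positive amplitude), the
cycle explains ~62% of the log-scale variability, and testosterone
peaks around day 224 (mid August — the generating peak was day 227).
`seasonal_out/prediction_band.csv` contains the mean curve with its
75% and 95% credible bands for plotting.

`finhorm run` chains every stage (QC → validation → mixture → location
→ seasonal) from one hormone CSV and writes a JSON manifest that makes
the run bit-reproducible.

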