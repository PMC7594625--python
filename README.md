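# bloodmet

Bayesian excess-risk analysis of **pre-diagnostic blood gene expression**
for **breast-cancer metastasis**, built around a paired case-control
design: each breast-cancer case is matched to a healthy control processed
in the same batch, and the analysis works on the per-pair difference in
log2 expression, `x_g = log2(case) − log2(control)`, so shared technical
effects cancel.

The package is aimed at statisticians and bioinformaticians who want a
tested, fully synthetic-data-driven implementation of this analysis:
every stage — beadchip-style preprocessing, per-gene hierarchical model,
excess-risk summaries, gene-set ranking — can be exercised end to end
with known ground truth and no external data.

## The model

For one gene g, with metastasis status `y_i ∈ {0, 1}` of case i and
detection mode `s_i ∈ {screening, interval}` (interval cancers — found
clinically between mammography screens — are typically more aggressive,
so slopes are stratified by mode):

```
y_i        ~ Bernoulli(p_i)
logit(p_i) = α_{s_i} + β_{s_i} · x_i
α_s        ~ normal(−1, 1)
β_s        ~ normal(μ, σ)            (partial pooling across modes)
μ          ~ normal(0, 0.1)
σ          = exp(σ′),  σ′ ~ normal(0, 0.2)
```

Sampling uses the non-centered parameterization `β_s = μ + σ·η_s` with a
slice-within-Gibbs MCMC (multiple independent chains, interleaved
centered/non-centered hyperparameter updates), with split-R̂ and bulk-ESS
diagnostics per gene.

After marginalizing (α, β) over the empirical detection-mode mixture,
the headline statistic is the **excess risk**

```
ρ_g = logit⁻¹(α_g + z·β_g) − logit⁻¹(α_g),     z = 0.1
```

— the absolute change in metastasis probability for a case whose
differential expression sits z standard deviations above average.  Genes
are ranked by the **sign probability** `p(ρ_g > 0)` (or `< 0`, matching
the sign of the median), a number in [0.5, 1]; gene sets (GMT format) are
ranked by the average sign probability of their measured members.

## Worked example

```python
import bloodmet as bm

# simulate 40 genes x 300 pairs from the model's own prior hierarchy
params = bm.simulate_parameters(40, seed=1)
diff, design, truth = bm.simulate_differential_cohort(params, 300, seed=1)

s = design.pair_frame()["detection_mode"].to_numpy()
w = bm.estimate_detection_weights(design)
cfg = bm.GeneModelConfig(chains=2, warmup=250, draws=500, seed=1)

fit = bm.fit_gene_model(diff.gene("G0001"),
                        truth["y_matrix"].loc["G0001"].to_numpy(), s, cfg,
                        gene="G0001")
summary = bm.summarize_gene(fit, w, seed=1)
print(f"{summary.gene}: median rho {summary.rho_median:+.4f}, "
      f"sign prob {summary.sign_prob:.3f}, direction {summary.direction}")
print(f"true beta_screen {params.beta_screen[0]:+.3f}, "
      f"posterior mean {fit.stacked('beta_screen').mean():+.3f}")
```

prints

```
G0001: median rho +0.0278, sign prob 1.000, direction up
true beta_screen +1.298, posterior mean +1.235
```

i.e. higher expression of this gene raises the absolute metastasis risk
by about 2.8 percentage points (per 0.1 SD of differential expression)
at the posterior median, the posterior is certain of the direction (sign
probability 1.0), and the true screening-stratum slope of 1.30 is
recovered at 1.24 — slightly shrunk toward the pooled prior, as the
partial pooling intends.  The whole pipeline (preprocessing from raw
probe intensities, all genes, gene-set tables, audit log and manifest)
runs as

```
bloodmet run-all --seed 1 --out-dir results/demo
```

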