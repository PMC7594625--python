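# Methods

## Study design and data model

The package analyses a paired case-control design for breast-cancer
metastasis: women who developed breast cancer within a short window after
giving a blood sample, each matched to a healthy control of the same age
whose sample was processed in the same laboratory batch.  The outcome is
lymph-node metastasis at diagnosis (y = 1) versus none (y = 0); the
predictor for gene g is the within-pair difference in log2 expression,
standardized per gene to mean zero and unit SD.  Because both members of
a pair share a batch, any additive batch effect on the log scale cancels
exactly in the difference; this is the design's main protection against
technical variation and the reason the analysis never models batches
explicitly.

Detection mode — screening-detected versus interval-detected cancer — is
used as a proxy for tumour aggressiveness and stratifies the model:
screening and interval cancers get separate intercepts and slopes, with
the slopes partially pooled.

## Preprocessing

Raw probe intensities go through: (1) per-sample background subtraction
of the mean negative-control intensity, floored at 1.0 so log2 stays
defined; (2) log2; (3–4) a detection filter — a probe counts as detected
in a sample when fewer than 1% of that sample's negative controls reach
its intensity (empirical exceedance), and probes detected in fewer than
15% of samples are dropped, with the exact-15% boundary retained; (5–7)
removal of probes with low annotation quality and collapse of duplicate
probes per gene symbol keeping the largest inter-quartile range (IQR ties
keep the first probe in input order, logged); (8) per-pair differential
expression.  A low-variation filter then removes genes with
|mean| > 20 × SD on the differential scale (the absolute value matters
because differential means can be negative; genes with SD exactly zero
are removed as degenerate), and the survivors are standardized per gene
using the population-SD convention (divide by n).  Every step logs its
removal count into an audit trail whose totals must reconcile.

Design choices where several readings were possible: the detection
p-value is defined reproducibly from the bundle alone rather than
imported from scanner software; steps 3–4 are implemented as the single
rule "detected (p < 0.01) in ≥ 15% of samples"; the population-SD
standardization makes small worked examples exact and is a one-line
change to the sample-SD convention.

## The per-gene model and its sampler

The hierarchical logistic model (README) has six free quantities per
gene: α_screen, α_interval, β_screen, β_interval, μ, σ.  Priors:
α_s ~ N(−1, 1) centers the baseline risk near logit⁻¹(−1) ≈ 27%, the
typical metastasis fraction in this population; μ ~ N(0, 0.1) and
σ = exp(N(0, 0.2)) (a lognormal scale) keep per-gene slopes modest while
allowing the two strata to differ.  The prior-implied excess risk at
z = 0.1 is sharply peaked at zero with its central 60% spanning about
±0.014 — the prior treats absolute risk shifts beyond ~1.4 percentage
points per 0.1 SD of expression as unusual, providing mild shrinkage
toward the null.

Sampling uses the non-centered parameterization β_s = μ + σ·η_s,
η_s ~ N(0, 1) (η is internal; only β is exposed).  The sampler is
slice sampling within Gibbs (Neal 2003): each of the six coordinates is
updated by univariate slice sampling with stepping out (widths of order
the prior scales; the procedure is rejection-free and needs no step-size
tuning).  Each Gibbs sweep is followed by an interweaved
centered-parameterization update: holding β_s fixed, (μ, log σ) are
redrawn from their conditional — prior times ∏_s N(β_s; μ, σ), with no
data term — and η_s is back-solved.  This ancillarity–sufficiency
interweaving removes the funnel coupling between the slope scale and the
auxiliaries; empirically it raises the bulk ESS of σ from ~100 to several
hundred per 600 draws, and on long runs all six parameters reach
near-iid efficiency.

Defaults: 4 chains × (1000 warmup + 1000 draws), thresholds split-R̂
≤ 1.01 and bulk ESS ≥ 400 (arviz).  Genes failing diagnostics are
flagged and excluded from rankings, never silently dropped or re-run.
Chains derive independent streams from a per-gene seed computed from the
global seed and the gene index, so serial and parallel execution are
byte-identical.  The pipeline's default convergence floor adapts to the
configured draw count (min(400, half the total draws)) so that
deliberately small desk-scale runs still report meaningful pass/fail
flags.

Validation of the sampler is two-route: small instances (n ≤ 20) are
checked against an independent dense-grid quadrature oracle
(`tests/grid_oracle.py`) that integrates the unnormalized posterior on a
grid — conditional on (μ, log σ) the strata factorize, so the
(α_s, β_s) likelihood table is computed once and reweighted by the
N(μ, σ) slope prior across a 41×41 outer grid — agreeing with MCMC
moments to well under 0.05; and calibration is checked globally: on data
simulated from the prior, 90% credible intervals for β_s cover the truth
at the nominal rate.

## Risk statistics

Stratum marginalization treats "α ~ Σ_s p(s) α_s" as a mixture: for each
posterior draw a stratum is selected with probability p(s) (empirical
case proportions by detection mode, the only weights recoverable from
the design) and that stratum's (α, β) pair is taken jointly — not a
per-draw weighted average of parameters, which would understate
between-stratum uncertainty.  Excess risk ρ is evaluated per draw;
z = 0.1 by default because typical between-group mean differences on the
standardized scale are of that order; ρ is monotone in β with
sign(ρ) = sign(β).  Sign probability counts draws on the median's side
of zero; draws exactly at zero count on neither side (probability zero
for continuous posteriors).  Gene rankings sort by sign probability
descending, ties by |median ρ| then symbol.  The classical comparison
refits each stratum by unpenalized logistic maximum likelihood, combines
point estimates with the detection weights, and evaluates ρ at the
combined estimate; perfect separation (detected by non-convergence or
parameter blow-up past |20|) flags the gene out of the comparison.  On
prior-consistent simulations the posterior median |ρ| is smaller than
the MLE |ρ| on average — the expected mild shrinkage toward null.

Gene sets are scored by the plain average of member sign probabilities
over members measured in the expression matrix; unmeasured members carry
no evidence and are excluded (the measured count is reported so the
choice is auditable; the alternative of imputing 0.5 would only dilute
scores toward 0.5).  No enrichment statistic or multiplicity control is
computed — the method deliberately ranks rather than tests.

## The synthetic-data generator

Two layers.  The cohort layer draws gene-level parameters exactly from
the prior hierarchy, then simulates detection modes (screening with
probability 111/156 ≈ 0.71, matching the case composition of the study
design this emulates), standardized differential expression x ~ N(0, 1),
and outcomes either per gene (single-gene marginal mode, the default,
matching the independent single-gene regressions and used for
parameter-recovery and calibration tests) or from one designated causal
gene set.  A fully degenerate hyperprior (all scales zero) collapses
every parameter to its prior mean — slopes included — giving a
deterministic parameter set for exact tests.

The raw layer emulates beadchip input: log-normal signal around a
per-probe baseline (~2^12 fluorescence units) plus additive background
drawn from the same distribution as the negative controls (~100 units,
lognormal); pair-level log2 offsets shared by case and control emulate
batch effects that must cancel.  Gene categories are generated in known
counts: probes at half background level (undetectable everywhere), probes
detected in ⌈0.15·n⌉−1 samples (just under the rare-gene boundary),
low-annotation-quality probes, near-constant genes (a +1.0 log2 shift
with ~0.01 SD noise, safely beyond the 20× rule), and duplicated genes
whose three probes scale a single shared deviate by amplitudes
0.3/0.6/1.2 so the IQR order — and the collapse survivor — is
deterministic.  The generator writes a ledger of expected survivor
counts per filter; preprocessing must reproduce it exactly.

What the generator does **not** emulate: scanner physics, bead-level
replicates, RNA degradation, covariate-driven confounding, and any
realistic correlation structure between genes (genes are independent
given the design).  Passing tests therefore demonstrate the statistical
machinery — filters, calibration, shrinkage, ranking — not robustness to
the correlated, batch-confounded structure of real cohort data.

## Problem sizes and numerical choices

Simulation sizes are chosen to be desk-scale: calibration and shrinkage
experiments use 200 genes × 200 pairs at 2 chains × (250 + 400) draws;
quadrature comparisons use n ≤ 20 with 4 chains × 1500 draws; the
end-to-end pipeline demo uses 15–30 genes.  The quadrature oracle uses
41 outer grid points per hyperparameter over ±5 prior SDs and a
61 × 121 (α, β) inner grid; Riemann summation on these smooth integrands
is accurate far below the 0.05 comparison tolerance.  Slice-sampler
stepping out is capped at 100 doublings (never reached in practice).
Floors and boundaries: background-corrected intensities floor at 1.0;
the detection filter keeps the exact-15% boundary; excess-risk draws lie
strictly inside (−1, 1).

## Known limitations

Per-gene models are fit independently; there is no information sharing
across genes beyond the fixed prior, and no covariate adjustment inside
the gene model (intercept and one slope only).  The detection-weight
estimate treats the case mix as fixed rather than uncertain.  Sign
probability deliberately measures directional certainty, not magnitude —
a gene with a minuscule but precisely estimated ρ can outrank one with a
large uncertain ρ.
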