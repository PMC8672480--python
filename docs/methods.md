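# Methods

## The generative model

`scpopsim` simulates counts for a cohort of individuals in two stages.

**Stage 1 — means per gene per individual.** Population-wide gene means are
gamma distributed, λ_i ∼ Gamma(α_m, β_m). With probability `out_prob` a gene
is an expression outlier: its mean is replaced by median(λ) times a
log-normal factor. Between-individual variability is parameterized as a
coefficient of variation σ_i ∼ Gamma(α_v, β_v · s_v), with one (α_v, β_v)
pair per gene-mean bin so that the empirical mean-variance trend is
respected; the similarity scale s_v multiplies the rate, so doubling s_v
halves the expected cv. Individual baseline means are normal,
λ_ij ∼ N(λ_i, sd = λ_i σ_i). σ_i is a *coefficient of variation* — fit to
sd/mean ratios — so λ_i σ_i is the standard deviation of that normal, not
its variance; negative draws are floored at zero. When the population
parameters were estimated from bulk expression (`PopParams.bulk_derived`),
each individual's means are quantile-normalized onto Gamma(α_sc, β_sc), the
single-cell gene-mean distribution, using plotting positions
(rank − 0.5)/n with average ranks for ties.

cis effects are applied multiplicatively, λ_ij ← λ_ij (1 + G_ij ω_i), with
ω_i ∼ Gamma(α_e, β_e) strictly positive and G the minor-allele dosage.
Group-specific effects touch only that group's slice of the
genes × individuals × groups tensor; condition-specific effects touch only
the columns of cohort members. DE factors are log-normal, inverted to 1/f
with the configured down-probability, and multiply group slices (per-group
DE) or cohort columns (condition DE). The order of operations is: base
means (with outliers) → cv → individual means → quantile normalization →
eQTL → DE. Everything sampled is recorded in the simulation key; the key,
the genotypes and the master seed reproduce a run bit-exactly.

**Stage 2 — counts per cell.** Batches are filled from a shuffled roster of
individuals; slots beyond the cohort size become technical replicates drawn
uniformly from individuals not already in the batch. Batch factors are
log-normal per gene per batch and bidirectional (reciprocal with
probability 0.5, matching the usual multiplicative batch-factor
convention). Expected library sizes are log-normal; each cell's mean vector
is its individual/group slice times the batch factor, rescaled to sum to
the library size — the absolute scale of gene means therefore cancels, and
only relative expression is identified. Overdispersion enters through the
effective BCV, B_ic = (bcv_common + 1/√μ_ic)·√(bcv_df/χ²), with one
χ²(bcv_df) draw per gene (an option switches to per-entry draws); the mean
is mixed through Gamma(1/B², μB²) and the count is Poisson. Dropout, when
enabled, zeroes entries with probability expit(shape·(ln μ − mid)); with
the conventional negative shape, the keep-probability is an increasing
logistic function of the log mean.

## Parameters and defaults

| family | parameter | default | meaning |
|---|---|---|---|
| sc | α_sc, β_sc | 0.6, 0.3 | gamma of single-cell gene means |
| sc | lib_loc, lib_scale | 11, 0.2 | ln expected library size (≈ 60k counts) |
| sc | out_prob, out_loc, out_scale | 0.05, 4, 0.5 | expression outliers |
| sc | bcv_common, bcv_df | 0.1, 60 | overdispersion level / stability |
| sc | dropout (mid, shape) | off; 0, −1 | logistic dropout in ln-mean |
| pop | α_m, β_m | 0.34, 0.008 | population gene-mean gamma (mean ≈ 42) |
| pop | cv bins | 10 bins, cv 0.85 → 0.30 | mean-binned cv gammas (shape 8) |
| pop | s_v | 1 | similarity scale |
| eqtl | α_e, β_e | 3.6, 12 | effect-size gamma (mean 0.3) |
| eqtl | eqtl_prob, coreg_prop | 0.5, 0 | eGene share; shared-eSNP share |
| eqtl | maf bounds, dist_max | 0.05–0.5, 1 Mb | eSNP eligibility |
| de | de/cde prob, loc, scale | 0.1, 0.1, 0.4 | log-normal DE factors |
| design | batch_loc/scale | 0.1, 0.1 | per-batch factor distribution |

The population and eQTL defaults emulate a bulk tissue cohort: strongly
right-skewed means, a cv that declines with expression, and |effect sizes|
centred near 0.3. They are embedded constants chosen to be realistic for
such cohorts, not a fit to any specific public dataset.

## Estimation from reference data

* **Population** (`estimate_population_params`): genes below 0.1 in more
  than half the individuals are excluded; a gamma MLE (method-of-moments
  start) is fit to the surviving gene means; genes are split into
  equal-count mean bins (default 10) and a gamma is fit to each bin's
  sd/mean ratios. Degenerate (zero-variance) inputs raise rather than
  returning infinite shapes.
* **eQTL** (`estimate_eqtl_params`): gamma fit to the magnitudes of ≥10
  finite effect sizes; sign flips are counted and logged.
* **Single cell** (`estimate_sc_params`): log-normal fit to per-cell
  totals; gamma fit to winsorized (upper/lower 10%) per-gene means of
  library-normalized counts by Cramér-von Mises minimum distance (robust
  to the heavy upper tail); outliers flagged where the log mean exceeds
  median + 2 MAD, their factors fit log-normally; BCV via a trended moment
  estimate of the quadratic overdispersion (df from matching the residual
  log-dispersion spread to a log-χ² variance); dropout by a logistic fit
  of zero-fraction against ln mean. Because cell means are rescaled to
  library sizes, the gene-mean gamma is identified only up to the
  library-size scale — self-consistency holds on that scale.

## Randomness

One master seed feeds named substreams (annotation, genotypes, eqtl, means,
variances, individuals, de, design, batch, lib, counts, dropout). Changing
single-cell parameters therefore leaves the gene-level ground truth
untouched — useful for simulating several "chemistries" over shared
biology — and identical configuration + seed reproduces outputs
byte-identically.

## Evaluation suite

Counts are aggregated per individual (mean, sum, or mean of log1p).
Variance explained is the one-way between-group share of the total sum of
squares per gene; silhouette widths use Euclidean distance on normalized
log counts with the chosen label as cluster. Pseudobulk DE is a two-sided
Wilcoxon rank-sum on summed counts with BH correction.

The cis-eQTL mapper is deliberately simple: mean-aggregated expression is
rank-inverse-normal transformed per gene ((rank − 0.5)/n positions), every
SNP within the window (default ±100 kb) is tested by OLS, and the top SNP
is kept. The top p-value is Sidak-corrected for the number of cis SNPs
tested — without this, min-of-p selection over ~100 SNPs makes nearly every
null gene "significant" — and BH runs across genes on the corrected values.
This analytic correction stands in for a permutation-based empirical null
and is mildly anti-conservative for correlated SNPs; with the unstructured
genotypes this package simulates, SNPs are independent and the correction
is essentially exact. No kinship or expression-PC covariates are fitted
(the synthetic genotypes carry no population structure); a covariate hook
residualizes both sides when supplied.

Two effect-size columns are reported. `beta_int`, the OLS slope on the
transformed scale, drives the p-value but confounds the effect with the
gene's noise level (it is ≈ ω/total-sd), so it cannot be compared across
genes. `beta` is the multiplicative effect size: the ω minimizing the
squared coefficient of variation of the dosage-deflated aggregate
y_j/(1 + G_j ω) — a method-of-moments inversion of the generative model
that is exact for noise-free multiplicative relationships and is the
number to compare against the simulated ω.

## What the generator does and does not emulate

Simulated genotypes are Binomial(2, f) dosages with uniform allele
frequencies — no linkage disequilibrium, relatedness or Hardy-Weinberg
departures — so mapping results transfer to real cohorts only up to LD
(with LD, the "top SNP" is an LD proxy and within-gene multiplicity
corrections become conservative). Gene-gene correlation beyond shared-eSNP
pairs, trajectory structure, UMI/read-level artifacts, ambient RNA and
doublets are not modeled. Passing tests therefore demonstrate correctness
of the generative machinery and calibration of the evaluation pipelines
under the stated model, not fidelity to any particular tissue.

## Numerical and design choices

* Gamma fits are MLE with moment initialization except the single-cell
  mean fit (CvM minimum distance); zero-variance inputs raise.
* Mean bins are equal-count (quantile) bins; simulated means outside every
  bin use the nearest bin.
* Genotype filtering keeps SNPs with MAF strictly greater than the
  threshold (a SNP at exactly the threshold is removed).
* eGene sampling is restricted a priori to genes with ≥1 eligible eSNP; a
  warning reports how many genes were ineligible. Co-regulated pairs are
  formed greedily among eGenes whose eligible-SNP sets intersect; partners
  share the eSNP but keep their own effect sizes. An optional sign-flip
  probability (default 0) exists for users who want bidirectional genetic
  effects; it is an extension beyond the core model.
* Batch factors apply before the library-size rescale; counts are stored
  sparse and intermediates are kept only on request to bound memory.
* Experiment sizes in the test suite (e.g. 504 genes × 100 individuals ×
  80 cells, three seeds) keep full runs in the tens of seconds while
  leaving the measured quantities stable to ±0.01–0.02.

## Known limitations

The BCV moment estimator is less efficient than a likelihood-based trended
dispersion fit and its df estimate is approximate. The Sidak gene-level
correction assumes independent tests; under LD it is conservative. The
dosage-deflation effect estimator assumes a single causal cis variant per
gene, which is true by construction here but not in real data.
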