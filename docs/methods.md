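# Methods

## Statistical model

Expression (or any scalar response) is modelled per gene as

    Y = Sex + Genotype + Sex×Genotype + Line(Genotype) + ε,

where Genotype ranges over the cluster genotypes (allele strings over
{+, −, CD}), and Line(Genotype) is a random blocking factor: lines are
independently derived transformants nested within genotype and measured
in both sexes. All inference is on least-squares means of genotype × sex
cells and linear contrasts of them.

For the balanced designs this framework targets, the REML solution has a
closed form through expected mean squares, and that is what the default
engine computes, vectorized across all genes simultaneously:

* LS-means are averages of line-cell means (equal to raw cell means
  under balanced replication);
* with m observations per line, `E[MS_line] = σ²ε + m·σ²L`, so
  `σ̂²L = max(0, (MS_line − MS_resid)/m)`;
* a contrast `Σ w·LSmean` has variance `c₁·MS_line + c₂·MS_resid` where
  the coefficients follow from which cells share lines. Between-genotype
  contrasts are tested against line-level error (lines are the
  experimental unit); contrasts whose weights cancel within lines (e.g.
  sex differences) fall through to residual error — the classic
  split-plot structure. Degrees of freedom are Satterthwaite on the
  mean-square combination.
* the Genotype F-test uses MS_Genotype / MS_line — the
  expected-mean-squares denominator.

An iterative REML fit (statsmodels `MixedLM`) is provided as
`fit_gene_model_reml` for unbalanced data; on balanced data with a
nonnegative line-variance estimate the two agree, which the test suite
verifies. When a design has a single line per genotype the random term
has zero degrees of freedom and is dropped with a warning; genotype
tests then use residual error. Under mild imbalance (e.g. samples
removed by QC) the closed form uses mean replicate counts and is an
approximation; heavily unbalanced data should use the iterative path.

Multiplicity: BH step-up FDR within each contrast family (niche × sex;
per-sex diversification and epistasis over the analysed gene set),
Holm step-down for phenotype post hocs. Both wrap standard
implementations and are checked against brute-force step-up/step-down
oracles in the tests.

## The dissection framework

Writing `ko` for the full knockout and `full` for the intact cluster,
each response is summarised per sex by:

* **Diversification** — ANOVA among the four single-paralog
  reinsertions only (`Y = Genotype + Line(Genotype) + ε`). Significance
  means the paralogs act differently on this response; otherwise their
  effects are considered redundant.
* **CoV** — SD/mean (sample SD, n−1) of the four single-reinsertion
  LS-means: a power-independent, graded redundancy measure. CoV < 0.2
  is reported as "highly redundant". By default the LS-means are
  back-transformed to the linear scale first (log-scale means can be
  ≤ 0, where SD/mean is undefined); `cov_scale="model"` keeps the
  modelling scale, and an undefined CoV is always reported as NA with a
  warning, never silently dropped.
* **Epistasis** — the single contrast
  `(full − ko) − Σ_p (single_p − ko)`, equivalently weights
  (+1, +3, −1, −1, −1, −1) on (full, ko, singles). Positive significant
  estimates are enhancing (the intact cluster exceeds the sum of its
  parts), negative suppressing.
* **Quadrants** — crossing the two FDR calls at 0.05:
  redundant/diverse × additive/epistatic.

Transcript dissection is restricted by default to genes belonging to at
least one transcriptional niche (the DEG sets defined against the
knockout), with a flag to analyse all genes. CD-allele genotypes are
excluded from niche estimation by default since the CD allele's
functional status is itself a finding, not an assumption; the simulator
has a `cd_effect_scale` switch for residual CD function.

The same arithmetic applies to phenotype-scale LS-means
(`dissect_phenotype`): genotype locations from the survival model (hours)
or logit-scale sex-ratio means, with a Wald F-test among the four
singles for diversification.

## Phenotype models

**Survival.** Death times under starvation are treated as exactly
observed (checks are frequent relative to the logistic scale; no
censoring). The model is a logistic location-scale regression on the raw
time axis — `time = Genotype + Line(Genotype) + ε`, logistic ε, common
scale — fitted by maximum likelihood (BFGS with analytic gradient;
covariance from the inverse observed information). Line(Genotype) is a
fixed, sum-to-zero-coded nested effect, so the genotype coefficient is
directly the LS-mean over lines; lines with fewer than two deaths are
pooled into their genotype with a warning. Mated females, virgin
females, and males are fitted separately by the caller.

**Sex ratio.** Female count out of total progeny per vial follows a
binomial logistic regression on Genotype + Line(Genotype). Vial-level
clustering is absorbed by a quasi-binomial dispersion estimated from
Pearson residuals (a perfect fit degenerates to unit scale); vials with
zero progeny are excluded with a warning. Reported alongside the model
LS-means is the descriptive progeny-weighted mean % female per genotype.

**Associations** (fecundity vs survival; progeny count vs % female) use
simple least squares with an F-test on the slope.

## Normalization

GeTMM: counts → reads per kilobase (RPK) → TMM scaling factors computed
on the RPK matrix → each sample scaled to one million effective RPK,
optionally log2(x + 0.5). The TMM step follows the original trimmed
mean of M-values procedure: reference = sample whose 75th-percentile
relative expression is closest to the mean of those percentiles; per
gene M (log2 ratio) and A (mean log2 abundance) over genes positive in
both samples; double trim (30% on M, 5% on A); inverse-delta-method
precision weights; factors renormalized to geometric mean one. The
implementation reproduces Bioconductor edgeR's factors to ten decimal
places on a composition-shifted fixture (frozen in the tests).

Trimmed-mean normalization assumes most genes are not differentially
expressed between samples. When a large fraction of genes shift in the
same direction (e.g. simulating only strong same-sign effects), the
trimmed mean is displaced and contrasts acquire a composition bias —
a property of the method, not an implementation artefact. Validation
simulations therefore embed signal genes at realistic fractions
(≤ 10%) in a null background, and use sign-balanced effect groups where
the scenario allows.

Downstream models run on log2(GeTMM + 0.5) by default (variance
stabilization for linear models); raw GeTMM is available via
`log2=False`.

Sample QC: within each sex, average-linkage hierarchical clustering on
1 − Pearson correlation; cutting into two clusters, samples in a
cluster holding < 25% of the group are flagged — provided the split is
unambiguous (top merge height > 3× the median of the other merge
heights), so a flat tree of equally similar samples yields no flags.
The pipeline additionally refuses to let QC empty an entire
genotype × sex cell.

## Networks

Biweight midcorrelation: values are median-centred and weighted by Tukey
biweights `w = (1 − u²)²·1[|u| < 1]` with `u = (x − med)/(9·MAD)`; the
support is widened so that at most 10% of samples per side receive zero
weight (the `maxPOutliers` convention). Genes with zero MAD fall back to
Pearson with a warning. Soft-threshold powers 1–20 are scanned on the
unsigned adjacency `|bicor|^power`; the scale-free fit index is the R²
of log10 density vs log10 connectivity over **10 equal-width bins**,
signed by the slope. Equal-width binning is used because with
equal-count bins the frequency response is constant by construction and
the regression degenerates. The chosen power is the smallest reaching
fit ≥ 0.8, else the argmax. Edge lists apply a hard threshold on
|bicor| (configurable; no canonical default is asserted); hubs are the
top ⌈10%⌉ of network genes by retained-edge count, ties broken by
summed |correlation| then gene id for determinism. Named genotype-subset
presets (intact + knockout, plus the relevant reinsertions) select the
samples feeding each network.

## The simulator

`simulate_counts` draws NB counts (`Var = μ + φμ²`; Gamma–Poisson
mixture, exactly Poisson at φ = 0) around
`log2 μ = baseline + sex effect + Σ_p 1[p functional]·β_p + 1[intact]·δ
+ line effect`, scaled by per-sample library sizes. Under this
construction the epistasis contrast's true value is exactly δ and the
full-cluster effect is Σβ + δ, so recovery is directly checkable.
Defaults chosen once as realistic study conditions: baseline log2 mean
Uniform(4, 9) (≈ 16–512 expected counts), dispersion φ = 0.05, line SD
0.1 log2, library sizes log-normal around 10⁶ (log-SD 0.2), gene
lengths Uniform(500, 5000) bp, 8 genotypes × 2 sexes × 2 lines × 3
replicate pools. Line effects are drawn once per (gene, line) and
shared across sexes and replicates, matching the Line(Genotype)
blocking structure. `simulate_survival` and `simulate_sex_ratio` use
genotype parameter maps whose defaults reproduce the reference study's
printed values (e.g. 32% female offspring for the knockout, 46% for the
intact cluster; 44.6 h mean death time for starvation-sensitive mated
females) with documented choices where values were not printed.

What the simulator does **not** emulate: read-level artefacts (mapping,
GC/length bias beyond the static length factor), correlated
co-expression modules unless explicitly constructed, batch effects, and
any transcriptome-wide consequence of the CD allele beyond the
functional/non-functional switch. Passing tests therefore demonstrate
correctness of the estimators and error control under the stated
generative model, not robustness to every artefact of real RNA-seq.

## Problem sizes and numerical choices

Validation scenarios are sized for desk-scale runs: ~2,000 genes × 96
samples per simulated experiment, 200 replicates for survival/sex-ratio
recovery, 1,000 random vectors for the multiplicity oracles. Degenerate
inputs are handled explicitly: constant responses yield NA p-values
(flagged, not errors); an all-zero sample is an error naming the
sample; a singular phenotype design raises rather than silently
dropping cells. Survival times are floored just above zero rather than
rejection-sampled (at the study's locations and scale, negative draws
are vanishingly rare, and the scale→0 limit reproduces locations
exactly). Seeds propagate explicitly through every stochastic function;
identical seed and configuration give byte-identical outputs.
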