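# paralogdissect

Functional dissection of tandem paralog clusters from deletion–reinsertion
experiments.

## The problem

Tandemly duplicated genes — for example a cluster of four odorant-binding
protein paralogs in *Drosophila* — can retain overlapping (redundant)
functions, diverge, or interact epistatically. A deletion–reinsertion
design makes these questions experimentally tractable: the whole cluster
is deleted and engineered versions are reinserted at the endogenous locus
in which **all** paralogs are functional (`++++`), **none** are (`----`),
exactly **one** is (`+---`, `-+--`, `--+-`, `---+`), or one carries
conserved-residue substitutions (`CD` allele). Comparing these genotypes
on transcriptome-wide expression and on organismal phenotypes quantifies,
per response, how the paralogs divide labour.

`paralogdissect` implements the full analysis chain for such experiments,
plus a simulator with known ground truth to validate every step:

* **Design & simulation** — genotype × sex × line × replicate layouts;
  negative-binomial counts with per-paralog log2 effects `β`, a
  full-cluster epistasis deviation `δ`, sex effects, line-level variation
  (`Var = μ + φμ²`); logistic death times; binomial vial sex ratios.
* **Preprocessing** — gene filtering (≥ 25% nonzero samples and median
  count ≥ 2), GeTMM normalization (reads-per-kilobase scaled by
  trimmed-mean-of-M-values factors to one million), hierarchical-clustering
  sample QC.
* **Per-gene mixed ANOVA** — `Y = Sex + Genotype + Sex×Genotype +
  Line(Genotype) + ε` with Line(Genotype) random; LS-means, general
  cell contrasts with Satterthwaite df, BH-FDR and Holm corrections.
  Vectorized over thousands of genes.
* **Transcriptional niches** — per sex, the DEG set of each
  single-paralog reinsertion (and the intact cluster) against the full
  knockout at FDR < 0.05, with up/down direction.
* **Dissection** — the core framework, applicable to transcripts and
  scalar phenotypes alike:
  * *diversification test*: ANOVA among the four single reinsertions —
    a significant Genotype term means the paralogs act differently;
  * *CoV*: SD/mean of the four single-reinsertion LS-means, a graded
    redundancy measure (CoV < 0.2 reported as highly redundant);
  * *epistasis contrast*:
    `(full − ko) − Σ_p (single_p − ko) = full + 3·ko − Σ_p single_p`;
    significant positive estimates are **enhancing**, negative
    **suppressing** epistasis;
  * quadrant classification: redundant/diverse × additive/epistatic.
* **Phenotype models** — logistic accelerated-failure-time model on raw
  death times with Holm post hocs; quasi-binomial logistic regression of
  vial sex ratios; OLS association tests.
* **Networks** — unsigned biweight midcorrelation (outlier cap 10%),
  scale-free soft-threshold scan, hard-threshold edge lists, top-10% hub
  genes.

## Worked example

```python
import numpy as np
from paralogdissect import (
    DesignConfig, CountTruthConfig, simulate_design, simulate_counts,
    filter_genes, getmm_normalize, dissect_transcripts,
)

meta = simulate_design(DesignConfig())           # 96 samples
delta = np.zeros(600); delta[:40] = -2.0         # suppressing epistasis
counts, lengths, truth = simulate_counts(
    meta, CountTruthConfig(n_genes=600, epistasis_delta=delta, seed=4))
expr = getmm_normalize(filter_genes(counts), lengths)
table = dissect_transcripts(expr, meta, sexes=("M",),
                            genes=[f"gene{i+1:04d}" for i in range(60)])
print(table["quadrant"].value_counts())
```

Running `examples/04_dissection.py` (a richer version of the above)
prints:

```
quadrant
redundant-additive     25
diverse-additive       20
redundant-epistatic    13
diverse-epistatic       2

    gene  divers_fdr   cov  epi_estimate  epi_fdr            quadrant epistasis_direction
gene0001       0.005 0.862         0.282    0.736    diverse-additive                none
gene0026       0.748 0.095         1.137    0.252  redundant-additive                none
gene0046       0.623 0.120        -2.445    0.000 redundant-epistatic         suppressing
```

Gene 1 was simulated with its effect concentrated in one paralog: it is
called diverse (diversification FDR 0.005, CoV 0.86). Gene 26 has four
equal effects: redundant and additive (CoV 0.10). Gene 46 has equal
effects plus `δ = −2`: the epistasis contrast recovers −2.4 log2 and the
gene is labelled redundant-epistatic, suppressing.

The other scripts in `examples/` walk through simulation, normalization
and QC, niche calling, survival and sex-ratio phenotype models, and
network construction, each printing what it computes and what the
numbers mean. A thin CLI (`paralogdissect simulate | preprocess | all`)
drives the whole pipeline from a shell and writes TSV outputs plus a
manifest.

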