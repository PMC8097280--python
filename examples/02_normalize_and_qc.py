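"""Filter, GeTMM-normalize, and QC a count matrix.

Weakly expressed genes (under 25% nonzero samples or median count < 2)
are dropped; counts become length-corrected, TMM-scaled log2 values; and
hierarchical clustering flags samples that do not group with their sex.
"""

import numpy as np

from paralogdissect import (
    CountTruthConfig,
    DesignConfig,
    filter_genes,
    flag_outlier_samples,
    getmm_normalize,
    simulate_counts,
    simulate_design,
)

meta = simulate_design(DesignConfig())
counts, lengths, _ = simulate_counts(meta, CountTruthConfig(n_genes=300, seed=2))

filtered = filter_genes(counts)
print(f"filtering: {counts.shape[0]} -> {filtered.shape[0]} genes retained")

expr = getmm_normalize(filtered, lengths)  # log2(GeTMM + 0.5)
print(f"normalized matrix: {expr.shape}, transform = {expr.attrs['transform']}")
print("per-sample mean log2 expression (first 4):")
print(expr.mean(axis=0).head(4).round(3).to_string())

# corrupt one sample so the QC has something to find
expr_bad = expr.copy()
rng = np.random.default_rng(0)
expr_bad.iloc[:, 0] = rng.permutation(expr_bad.iloc[:, 0].to_numpy())
sex = meta.set_index("sample_id").loc[expr_bad.columns, "sex"]
flagged = flag_outlier_samples(expr_bad, sex)
print(f"\nQC flagged (expression profile scrambled on purpose): {flagged}")
# A flagged sample fell into a tiny cluster when its sex's samples were
# cut into two groups - the criterion for exclusion before modeling.
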