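import numpy as np
import pandas as pd
import pytest

from paralogdissect.design import DesignConfig, simulate_design
from paralogdissect.simulate import CountTruthConfig, simulate_counts


@pytest.fixture(scope="session")
def default_meta() -> pd.DataFrame:
    """The reference design: 8 genotypes x 2 sexes x 2 lines x 3 reps."""
    return simulate_design(DesignConfig())


@pytest.fixture(scope="session")
def null_experiment(default_meta):
    """A no-effect experiment: 400 genes, NB noise, line effects only."""
    cfg = CountTruthConfig(n_genes=400, seed=11)
    counts, lengths, truth = simulate_counts(default_meta, cfg)
    return counts, lengths, truth


def make_exact_expression(meta: pd.DataFrame, cell_values: dict, genes=("g1",)):
    """Noise-free expression: every sample takes its (genotype, sex) cell value.

    Useful for checking contrast arithmetic exactly.
    """
    data = {
        s: [cell_values[(g, x)] for _ in genes]
        for s, g, x in zip(meta["sample_id"], meta["genotype"], meta["sex"])
    }
    return pd.DataFrame(data, index=list(genes), dtype=float)
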