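"""Count filtering, GeTMM normalization, and sample-level QC.

GeTMM is gene-length-corrected TMM: raw counts are converted to reads per
kilobase (RPK), trimmed-mean-of-M-values scaling factors are computed on
the RPK matrix, and each sample is scaled to a million effective RPK.
The TMM step follows the original description: per-gene log ratios (M)
and average log abundances (A) against a reference sample, double
trimming (30% on M, 5% on A by default), and an inverse-delta-method
variance weighted mean of the surviving M values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "filter_genes",
    "rpk",
    "NormFactors",
    "tmm_factors",
    "getmm_normalize",
    "flag_outlier_samples",
]


def filter_genes(
    counts: pd.DataFrame,
    min_nonzero_fraction: float = 0.25,
    min_median: float = 2.0,
) -> pd.DataFrame:
    """Drop weakly expressed genes.

    A gene is retained when at least ``min_nonzero_fraction`` of its
    samples are nonzero AND its median count is at least ``min_median``.
    Idempotent: refiltering a filtered matrix changes nothing.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("count matrix is empty")
    values = counts.to_numpy()
    nonzero_frac = (values > 0).mean(axis=1)
    medians = np.median(values, axis=1)
    keep = (nonzero_frac >= min_nonzero_fraction) & (medians >= min_median)
    logger.info(
        "filter_genes: retained %d/%d genes (nonzero fraction >= %.2f and median >= %g)",
        int(keep.sum()),
        len(keep),
        min_nonzero_fraction,
        min_median,
    )
    return counts.loc[keep]


def rpk(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Reads per kilobase: count / (length / 1000)."""
    missing = counts.index.difference(lengths_bp.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene lengths for: {list(missing[:5])} ...")
    lengths = lengths_bp.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return counts.div(lengths / 1000.0, axis=0)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and RPK library sums.

    Factors are renormalized to geometric mean one, so they encode
    composition differences only; depth is carried by ``lib_sizes``.
    """

    factors: pd.Series
    lib_sizes: pd.Series
    reference_sample: str


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool = True,
) -> float:
    """TMM log2 factor of one sample against the reference."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 0.0
    fo = obs[both] / lib_obs
    fr = ref[both] / lib_ref
    m = np.log2(fo / fr)
    a = 0.5 * np.log2(fo * fr)
    if np.allclose(np.max(m), np.min(m)):
        return float(m[0])
    # inverse asymptotic variances of M (delta method on two binomials)
    w = (lib_obs - obs[both]) / (lib_obs * obs[both]) + (lib_ref - ref[both]) / (
        lib_ref * ref[both]
    )
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    if weighted:
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    else:
        f = np.mean(m[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    rpk_matrix: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
    weighted: bool = True,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors on an RPK matrix.

    The reference is the sample whose 75th-percentile relative expression
    is closest to the mean of those percentiles, unless given.  Factors
    are invariant to gene order and to a common rescaling of all samples,
    and are renormalized to geometric mean one.
    """
    if rpk_matrix.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    values = rpk_matrix.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    zero_cols = np.nonzero(lib <= 0)[0]
    if zero_cols.size:
        bad = rpk_matrix.columns[zero_cols[0]]
        raise ValueError(f"sample {bad!r} has no positive expression")
    if reference is None:
        q75 = np.array(
            [np.quantile(values[:, j] / lib[j], 0.75) for j in range(values.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = rpk_matrix.columns.get_loc(reference)
    log_factors = np.array(
        [
            _tmm_pair(
                values[:, j], values[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a,
                weighted,
            )
            for j in range(values.shape[1])
        ]
    )
    factors = 2.0 ** (log_factors - log_factors.mean())  # geometric mean 1
    return NormFactors(
        factors=pd.Series(factors, index=rpk_matrix.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=rpk_matrix.columns, name="rpk_lib_size"),
        reference_sample=str(rpk_matrix.columns[ref_idx]),
    )


def getmm_normalize(
    counts: pd.DataFrame,
    lengths_bp: pd.Series,
    factors: NormFactors | None = None,
    log2: bool = True,
    offset: float = 0.5,
) -> pd.DataFrame:
    """GeTMM normalization: RPK scaled per million of TMM-adjusted library.

    ``value[g,s] = rpk[g,s] / (rpk_libsize_s * factor_s) * 1e6``, then
    optionally ``log2(value + offset)``.  With unit factors each column
    sums to one million before the log transform.
    """
    r = rpk(counts, lengths_bp)
    if factors is None:
        factors = tmm_factors(r)
    denom = factors.lib_sizes.reindex(r.columns) * factors.factors.reindex(r.columns)
    if (denom <= 0).any():
        bad = denom.index[denom <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive effective library size")
    expr = r.div(denom, axis=1) * 1e6
    if log2:
        expr = np.log2(expr + offset)
    expr.attrs["transform"] = f"log2(getmm+{offset})" if log2 else "getmm"
    return expr


def flag_outlier_samples(
    expr: pd.DataFrame,
    groups: pd.Series | None = None,
    max_cluster_fraction: float = 0.25,
) -> list[str]:
    """Hierarchical-clustering sample QC.

    Within each group (typically sex), samples are clustered by average
    linkage on distance 1 - Pearson correlation; cutting the tree into two
    clusters, any sample falling in a cluster holding fewer than
    ``max_cluster_fraction`` of the group's samples is flagged as not
    grouping unambiguously with the rest.  The split itself must be
    unambiguous: the top merge height must exceed ``min_separation`` times
    the median of the other merge heights, so a flat tree (all samples
    alike) yields no flags.
    """
    min_separation = 3.0
    if groups is None:
        groups = pd.Series("all", index=expr.columns)
    flagged: list[str] = []
    for name, cols in groups.groupby(groups).groups.items():
        sub = expr[list(cols)]
        if sub.shape[1] < 3:
            warnings.warn(
                f"group {name!r} has fewer than 3 samples; outlier QC skipped"
            )
            continue
        corr = np.corrcoef(sub.to_numpy().T)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        tree = linkage(squareform(dist, checks=False), method="average")
        heights = tree[:, 2]
        inner = np.median(heights[:-1]) if len(heights) > 1 else 0.0
        if heights[-1] <= min_separation * max(inner, 1e-12):
            continue  # flat tree: nothing groups ambiguously
        labels = fcluster(tree, t=2, criterion="maxclust")
        for k in np.unique(labels):
            members = np.nonzero(labels == k)[0]
            if len(members) < max_cluster_fraction * sub.shape[1]:
                flagged.extend(sub.columns[members])
    if flagged:
        logger.info("flag_outlier_samples: flagged %s", flagged)
    return flagged
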