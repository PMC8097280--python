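"""Unsigned biweight-midcorrelation co-expression networks.

The biweight midcorrelation (bicor) is a robust correlation: samples are
median-centred and weighted by Tukey biweights, so a few outlying
samples cannot dominate a gene pair's correlation.  The maximum
proportion of samples allowed to receive zero weight on either side is
capped (10% by default): if more than that fraction of samples would
fall outside the biweight support, the support is widened so that
exactly the capped quantile sits at its edge.

Soft thresholds for scale-free topology are scanned over integer powers
of the unsigned adjacency ``|bicor|^power``; edge lists for
visualisation use a hard threshold on ``|bicor|``, and hub genes are the
top 10% of network genes by retained-edge count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "bicor",
    "bicor_matrix",
    "pick_soft_threshold",
    "EdgeList",
    "build_edges",
    "call_hubs",
    "to_networkx",
    "NETWORK_PRESETS",
]

#: Genotype subsets feeding each named network: every network includes the
#: intact and knockout samples; single-paralog networks add their
#: reinsertion genotype, the cluster and dissection networks all four.
_BASE = ["++++", "----"]
_SINGLES = ["+---", "-+--", "--+-", "---+"]
NETWORK_PRESETS: dict[str, list[str]] = {
    "a": _BASE + ["+---"],
    "b": _BASE + ["-+--"],
    "c": _BASE + ["--+-"],
    "d": _BASE + ["---+"],
    "cluster": _BASE + _SINGLES,
    "dissection": _BASE + _SINGLES,
}


def _biweight_rows(values: np.ndarray, max_outlier: float) -> tuple[np.ndarray, np.ndarray]:
    """Median-centred, biweight-weighted, unit-norm rows.

    Returns (rows, pearson_fallback_mask).  Rows with zero median absolute
    deviation cannot be biweighted and fall back to standardised values.
    """
    n_genes, n_samples = values.shape
    med = np.median(values, axis=1, keepdims=True)
    centred = values - med
    mad = np.median(np.abs(centred), axis=1, keepdims=True)
    fallback = (mad == 0).ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        u = centred / (9.0 * mad)
    u[fallback] = 0.0

    # widen the support so at most max_outlier of samples per side get
    # zero weight
    if max_outlier < 0.5:
        q_low = np.quantile(u, max_outlier, axis=1, keepdims=True)
        q_high = np.quantile(u, 1.0 - max_outlier, axis=1, keepdims=True)
        low_div = np.maximum(-q_low, 1.0)
        high_div = np.maximum(q_high, 1.0)
        u = np.where(u < 0, u / low_div, u / high_div)

    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    rows = centred * w
    if fallback.any():
        mu = values[fallback].mean(axis=1, keepdims=True)
        rows[fallback] = values[fallback] - mu
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    zero = (norms == 0).ravel()
    norms[zero] = 1.0
    return rows / norms, fallback


def bicor_matrix(
    expr: pd.DataFrame, max_outlier: float = 0.10
) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs (genes in rows).

    Constant genes (zero median absolute deviation) fall back to Pearson
    correlation with a warning.  The result is symmetric with unit
    diagonal, values clipped to [-1, 1].
    """
    if expr.shape[1] < 4:
        raise ValueError("bicor needs at least 4 samples")
    rows, fallback = _biweight_rows(expr.to_numpy(dtype=float), max_outlier)
    if fallback.any():
        warnings.warn(
            f"{int(fallback.sum())} gene(s) with zero MAD: Pearson fallback "
            f"({list(expr.index[fallback][:5])})"
        )
    corr = np.clip(rows @ rows.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    out = pd.DataFrame(corr, index=expr.index, columns=expr.index)
    out.attrs["method"] = f"bicor(maxPOutliers={max_outlier})"
    return out


def bicor(x, y, max_outlier: float = 0.10) -> float:
    """Biweight midcorrelation of two vectors."""
    values = np.vstack([np.asarray(x, float), np.asarray(y, float)])
    rows, _ = _biweight_rows(values, max_outlier)
    return float(np.clip(rows[0] @ rows[1], -1.0, 1.0))


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) on log10(mean k) over equal-width bins, signed
    by the slope (positive fit requires a decreasing degree density)."""
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    counts = np.array([(which == b).sum() for b in range(len(edges) - 1)])
    mean_k = np.array(
        [k[which == b].mean() if c else 0.0 for b, c in enumerate(counts)]
    )
    freq = counts / k.size
    ok = (freq > 0) & (mean_k > 0)
    if ok.sum() < 3 or np.ptp(np.log10(mean_k[ok])) == 0:
        return float("nan")
    lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    corr: pd.DataFrame,
    powers=range(1, 21),
    target_fit: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Scan soft-threshold powers for scale-free topology.

    For each power, the unsigned adjacency is ``|corr|^power`` (no
    self-edges); connectivity is its row sum.  The fit index is the R^2
    of the log-log degree-density regression, signed so that only a
    decreasing density counts as scale-free.  Returns the smallest power
    reaching ``target_fit`` (else the argmax) and the full table.
    """
    if corr.shape[0] < 20:
        warnings.warn("fewer than 20 genes: scale-free fit is unreliable")
    a0 = np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(a0, 0.0)
    rows = []
    for p in powers:
        a = a0**p
        k = a.sum(axis=1)
        rows.append(
            {
                "power": int(p),
                "fit": _scale_free_fit(k, n_bins),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    if table["fit"].isna().all():
        warnings.warn("scale-free fit undefined at every power (degenerate k)")
        return int(table["power"].iloc[0]), table
    reaching = table[table["fit"] >= target_fit]
    if len(reaching):
        chosen = int(reaching["power"].iloc[0])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "power"])
    return chosen, table


@dataclass
class EdgeList:
    """Hard-thresholded network: retained edges and node degrees."""

    edges: pd.DataFrame  # source, target, correlation, sign
    nodes: pd.DataFrame  # gene, degree, sum_abs_corr, hub
    threshold: float


def build_edges(corr: pd.DataFrame, hard_threshold: float) -> EdgeList:
    """Retain gene pairs with ``|corr| >= hard_threshold`` (no self-edges)."""
    if not 0.0 <= hard_threshold <= 1.0:
        raise ValueError("hard threshold must be in [0, 1]")
    c = corr.to_numpy(dtype=float)
    genes = list(corr.index)
    iu = np.triu_indices(len(genes), k=1)
    keep = np.abs(c[iu]) >= hard_threshold
    src = [genes[i] for i in iu[0][keep]]
    tgt = [genes[j] for j in iu[1][keep]]
    vals = c[iu][keep]
    edges = pd.DataFrame(
        {
            "source": src,
            "target": tgt,
            "correlation": vals,
            "sign": np.where(vals >= 0, "+", "-"),
        }
    )
    degree = pd.Series(0, index=genes, dtype=int)
    strength = pd.Series(0.0, index=genes)
    for s, t, v in zip(src, tgt, np.abs(vals)):
        degree[s] += 1
        degree[t] += 1
        strength[s] += v
        strength[t] += v
    nodes = pd.DataFrame(
        {
            "gene": genes,
            "degree": degree.to_numpy(),
            "sum_abs_corr": strength.to_numpy(),
            "hub": False,
        }
    )
    return EdgeList(edges=edges, nodes=nodes, threshold=hard_threshold)


def call_hubs(edgelist: EdgeList, top_fraction: float = 0.10) -> list[str]:
    """Hub genes: the top ``ceil(top_fraction * n_nodes)`` by degree.

    Ties are broken by summed |correlation| of retained edges, then by
    gene id, so the call is deterministic.  Marks the ``hub`` flag on the
    node table and returns the hub genes.
    """
    nodes = edgelist.nodes
    if len(nodes) == 0:
        raise ValueError("empty network")
    n_hubs = math.ceil(top_fraction * len(nodes))
    ranked = nodes.sort_values(
        ["degree", "sum_abs_corr", "gene"], ascending=[False, False, True]
    )
    hubs = ranked["gene"].head(n_hubs).tolist()
    edgelist.nodes["hub"] = edgelist.nodes["gene"].isin(hubs)
    return hubs


def to_networkx(edgelist: EdgeList):
    """Export to a networkx Graph with node/edge attributes."""
    import networkx as nx

    g = nx.Graph()
    for row in edgelist.nodes.itertuples(index=False):
        g.add_node(row.gene, degree=int(row.degree), hub=bool(row.hub))
    for row in edgelist.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, correlation=float(row.correlation),
                   sign=row.sign)
    return g
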