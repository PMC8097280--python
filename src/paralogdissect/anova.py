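"""Per-gene mixed-model ANOVA with LS-means and general cell contrasts.

The model is ``Y = Sex + Genotype + Sex*Genotype + Line(Genotype) + e``
with Line(Genotype) a random blocking factor: lines are independently
derived within each genotype, measured in both sexes.  For the balanced
designs this machinery targets, the REML solution has a closed form via
expected mean squares, which is what :func:`fit_gene_models` computes,
vectorized over thousands of genes at once:

* LS-means of genotype x sex cells are averages of line-cell means
  (equal to raw cell means when replication is balanced);
* the line variance component is ``(MS_line - MS_resid) / m`` with ``m``
  observations per line, truncated at zero;
* a contrast ``sum w * LSmean`` has variance expressible as
  ``c1 * MS_line + c2 * MS_resid`` (lines are the experimental unit for
  between-genotype comparisons, residuals for within-line ones), with
  Satterthwaite degrees of freedom for the t test.

An iterative REML fit (statsmodels ``MixedLM``) is available through
:func:`fit_gene_model_reml` for unbalanced data and as an independent
cross-check; on balanced data with a nonnegative line variance estimate
the two agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneFitBundle",
    "ContrastResult",
    "fit_gene_models",
    "fit_gene_model",
    "fit_gene_model_reml",
    "ls_contrast",
    "bh_fdr",
    "holm",
]


@dataclass
class ContrastResult:
    """A linear combination of LS-means for one response."""

    label: str
    estimate: float
    se: float
    df: float
    t: float
    p: float


class GeneFitBundle:
    """Fits of the same design to many genes at once.

    Attributes
    ----------
    genes : list of gene ids
    cells : list of (genotype, sex) tuples defining the LS-mean columns
    lsmeans : (n_genes, n_cells) array
    ms_line, ms_resid : per-gene mean squares (ms_line is NaN when the
        line term was dropped)
    df_line, df_resid : shared degrees of freedom
    """

    def __init__(
        self,
        genes,
        cells,
        lsmeans,
        ms_line,
        df_line,
        ms_resid,
        df_resid,
        n_lines,
        n_reps,
        m_per_line,
        has_line_term,
        genotypes,
    ):
        self.genes = list(genes)
        self.cells = list(cells)
        self.lsmeans = lsmeans
        self.ms_line = ms_line
        self.df_line = df_line
        self.ms_resid = ms_resid
        self.df_resid = df_resid
        self.n_lines = n_lines  # genotype -> number of lines
        self.n_reps = n_reps  # (genotype, sex) -> replicates per line
        self.m_per_line = m_per_line  # observations per line
        self.has_line_term = has_line_term
        self.genotypes = list(genotypes)
        self._cell_index = {c: j for j, c in enumerate(self.cells)}
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    # -- accessors -------------------------------------------------------

    def lsmean_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.cells, names=["genotype", "sex"])
        return pd.DataFrame(self.lsmeans, index=self.genes, columns=cols)

    def sigma2_line(self) -> np.ndarray:
        """Line variance component, truncated at zero."""
        if not self.has_line_term:
            return np.zeros(len(self.genes))
        return np.maximum((self.ms_line - self.ms_resid) / self.m_per_line, 0.0)

    # -- inference -------------------------------------------------------

    def contrast(self, weights: dict, label: str = "contrast") -> pd.DataFrame:
        """Estimate ``sum w * LSmean`` for every gene.

        ``weights`` maps (genotype, sex) cells to real coefficients.
        Returns a DataFrame with estimate, SE, Satterthwaite df, t and
        two-sided p per gene.  Degenerate responses (zero variance) get
        NaN p.
        """
        for cell, w in weights.items():
            if cell not in self._cell_index:
                raise ValueError(f"contrast references absent cell {cell!r}")
            if w == 0:
                raise ValueError(f"zero weight on cell {cell!r}")
        west = np.zeros(len(self.cells))
        for cell, w in weights.items():
            west[self._cell_index[cell]] = w
        estimate = self.lsmeans @ west

        # variance coefficients on (MS_line, MS_resid)
        c1 = 0.0
        c2 = 0.0
        by_geno: dict[str, dict[str, float]] = {}
        for (g, s), w in weights.items():
            by_geno.setdefault(g, {})[s] = w
        for g, ws in by_geno.items():
            nl = self.n_lines[g]
            w_sum = sum(ws.values())
            within = sum(w**2 / self.n_reps[(g, s)] for s, w in ws.items())
            if self.has_line_term:
                c1 += w_sum**2 / (nl * self.m_per_line)
                c2 += (within - w_sum**2 / self.m_per_line) / nl
            else:
                c2 += within / nl
        if self.has_line_term:
            var = c1 * self.ms_line + c2 * self.ms_resid
            num = var**2
            den = np.zeros_like(var)
            if c1 > 0:
                den = den + (c1 * self.ms_line) ** 2 / self.df_line
            if c2 > 0:
                den = den + (c2 * self.ms_resid) ** 2 / self.df_resid
            with np.errstate(divide="ignore", invalid="ignore"):
                df = np.where(den > 0, num / den, np.nan)
        else:
            var = c2 * self.ms_resid
            df = np.full(len(self.genes), float(self.df_resid))
        var = np.maximum(var, 0.0)
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, estimate / se, np.nan)
            p = 2.0 * stats.t.sf(np.abs(t), df)
        return pd.DataFrame(
            {
                "gene": self.genes,
                "label": label,
                "estimate": estimate,
                "se": se,
                "df": df,
                "t": t,
                "p": p,
            }
        ).set_index("gene")

    def genotype_ftest(self) -> pd.DataFrame:
        """F-test of the Genotype term against its expected-mean-squares
        denominator: Line(Genotype) when the line term is present,
        residual otherwise.  Returns F, df, and p per gene."""
        lsm = self.lsmeans
        # genotype means: average LS-means over sexes
        geno_cols = {}
        for j, (g, s) in enumerate(self.cells):
            geno_cols.setdefault(g, []).append(j)
        G = len(geno_cols)
        geno_means = np.column_stack(
            [lsm[:, cols].mean(axis=1) for cols in geno_cols.values()]
        )
        n_per_geno = np.array(
            [
                self.n_lines[g]
                * sum(self.n_reps[(g, s)] for s in {c[1] for c in self.cells if c[0] == g})
                for g in geno_cols
            ]
        )
        grand = (geno_means * n_per_geno).sum(axis=1) / n_per_geno.sum()
        ss_g = ((geno_means - grand[:, None]) ** 2 * n_per_geno).sum(axis=1)
        ms_g = ss_g / (G - 1)
        if self.has_line_term:
            denom, df_den = self.ms_line, self.df_line
        else:
            denom, df_den = self.ms_resid, self.df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, ms_g / denom, np.nan)
            p = stats.f.sf(f, G - 1, df_den)
        return pd.DataFrame(
            {"F": f, "df_num": G - 1, "df_den": df_den, "p": p}, index=self.genes
        )


@dataclass
class GeneFit:
    """Single-gene view into a :class:`GeneFitBundle`."""

    gene: str
    bundle: GeneFitBundle

    @property
    def lsmeans(self) -> pd.Series:
        i = self.bundle._gene_index[self.gene]
        return pd.Series(
            self.bundle.lsmeans[i],
            index=pd.MultiIndex.from_tuples(
                self.bundle.cells, names=["genotype", "sex"]
            ),
        )

    @property
    def sigma2_line(self) -> float:
        return float(self.bundle.sigma2_line()[self.bundle._gene_index[self.gene]])

    @property
    def sigma2_resid(self) -> float:
        return float(self.bundle.ms_resid[self.bundle._gene_index[self.gene]])


def _check_balance(meta: pd.DataFrame) -> tuple[dict, dict, float]:
    """Verify per-cell replication is balanced; return design summaries."""
    n_lines = meta.groupby("genotype")["line"].nunique().to_dict()
    reps = meta.groupby(["genotype", "sex", "line"]).size()
    n_reps = {}
    for (g, s), grp in reps.groupby(level=[0, 1]):
        vals = grp.unique()
        if len(vals) > 1:
            warnings.warn(
                f"unbalanced replication in cell ({g}, {s}); closed-form fit "
                "uses the mean replicate count (consider the REML path)"
            )
        n_reps[(g, s)] = float(grp.mean())
    m_per_line = float(meta.groupby("line").size().mean())
    return n_lines, n_reps, m_per_line


def fit_gene_models(
    expr: pd.DataFrame, meta: pd.DataFrame, drop_line: bool | None = None
) -> GeneFitBundle:
    """Fit ``Y = Sex + Genotype + Sex*Genotype + Line(Genotype) + e`` to
    every row of an expression matrix simultaneously.

    ``expr`` columns must match ``meta['sample_id']``.  When every
    genotype has a single line (or ``drop_line=True``) the random term is
    dropped with a warning and residual error is used throughout.
    """
    meta = meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
    Y = expr.to_numpy(dtype=float)
    n_genes, n_obs = Y.shape

    n_lines, n_reps, m_per_line = _check_balance(meta)
    if drop_line is None:
        drop_line = all(v <= 1 for v in n_lines.values())
        if drop_line:
            warnings.warn(
                "single line per genotype: Line(Genotype) term has zero df "
                "and is dropped; genotype tests use residual error"
            )
    has_line = not drop_line

    cells = sorted(
        meta[["genotype", "sex"]].drop_duplicates().itertuples(index=False, name=None)
    )
    cell_of = {c: j for j, c in enumerate(cells)}
    cell_idx = np.array(
        [cell_of[(g, s)] for g, s in zip(meta["genotype"], meta["sex"])]
    )
    lines = sorted(meta["line"].unique())
    line_of = {l: j for j, l in enumerate(lines)}
    line_idx = np.array([line_of[l] for l in meta["line"]])
    genos = sorted(meta["genotype"].unique())
    geno_of = {g: j for j, g in enumerate(genos)}
    geno_idx = np.array([geno_of[g] for g in meta["genotype"]])
    geno_of_line = np.array(
        [geno_of[meta.loc[meta["line"] == l, "genotype"].iloc[0]] for l in lines]
    )

    def col_means(idx, k):
        sums = np.zeros((n_genes, k))
        np.add.at(sums.T, idx, Y.T)
        counts = np.bincount(idx, minlength=k).astype(float)
        return sums / counts, counts

    # line-cell means -> LS-means as averages of per-line means
    lc_idx_map = {}
    lc_idx = np.empty(n_obs, dtype=int)
    for i in range(n_obs):
        key = (cell_idx[i], line_idx[i])
        lc_idx[i] = lc_idx_map.setdefault(key, len(lc_idx_map))
    lc_means, lc_counts = col_means(lc_idx, len(lc_idx_map))
    lsmeans = np.zeros((n_genes, len(cells)))
    per_cell_nlines = np.zeros(len(cells))
    for (cj, lj), k in lc_idx_map.items():
        lsmeans[:, cj] += lc_means[:, k]
        per_cell_nlines[cj] += 1
    lsmeans /= per_cell_nlines

    line_means, line_counts = col_means(line_idx, len(lines))
    geno_means = np.zeros((n_genes, len(genos)))
    lines_per_geno = np.bincount(geno_of_line, minlength=len(genos)).astype(float)
    np.add.at(geno_means.T, geno_of_line, line_means.T)
    geno_means /= lines_per_geno

    # additive-line model fitted values: cell mean + line deviation
    fitted = (
        lsmeans[:, cell_idx]
        + line_means[:, line_idx]
        - geno_means[:, geno_idx]
    )
    if has_line:
        df_resid = n_obs - len(cells) - (len(lines) - len(genos))
        resid = Y - fitted
    else:
        df_resid = n_obs - len(cells)
        resid = Y - lsmeans[:, cell_idx]
    ss_resid = (resid**2).sum(axis=1)
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.full(n_genes, np.nan)

    if has_line:
        dev = line_means - geno_means[:, geno_of_line]
        ss_line = (dev**2 * line_counts).sum(axis=1)
        df_line = len(lines) - len(genos)
        ms_line = ss_line / df_line
    else:
        ms_line = np.full(n_genes, np.nan)
        df_line = 0

    return GeneFitBundle(
        genes=expr.index,
        cells=cells,
        lsmeans=lsmeans,
        ms_line=ms_line,
        df_line=df_line,
        ms_resid=ms_resid,
        df_resid=df_resid,
        n_lines=n_lines,
        n_reps=n_reps,
        m_per_line=m_per_line,
        has_line_term=has_line,
        genotypes=genos,
    )


def fit_gene_model(y, meta: pd.DataFrame, **kwargs) -> GeneFit:
    """Fit the mixed ANOVA to a single response vector."""
    name = getattr(y, "name", None) or "response"
    expr = pd.DataFrame(
        [np.asarray(y, dtype=float)], index=[name], columns=meta["sample_id"]
    )
    bundle = fit_gene_models(expr, meta, **kwargs)
    return GeneFit(gene=name, bundle=bundle)


def fit_gene_model_reml(y, meta: pd.DataFrame):
    """Iterative REML fit of the same model via statsmodels MixedLM.

    Slower than the closed form and intended for unbalanced designs or
    cross-validation of the vectorized path.  Returns the fitted
    ``MixedLMResults``.
    """
    import statsmodels.formula.api as smf

    df = meta.copy()
    df["y"] = np.asarray(y, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ C(sex) * C(genotype)", df, groups=df["line"])
        return model.fit(reml=True)


def ls_contrast(fit, weights: dict, label: str = "contrast") -> ContrastResult:
    """Contrast of genotype x sex LS-means for a single-gene fit."""
    if isinstance(fit, GeneFitBundle):
        raise TypeError("pass GeneFitBundle.contrast() for many genes")
    table = fit.bundle.contrast(weights, label=label)
    row = table.loc[fit.gene]
    return ContrastResult(
        label=label,
        estimate=float(row["estimate"]),
        se=float(row["se"]),
        df=float(row["df"]),
        t=float(row["t"]),
        p=float(row["p"]),
    )


# -- multiplicity corrections -----------------------------------------------


def _with_nan(p, adjust):
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = adjust(p[mask])
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    from statsmodels.stats.multitest import multipletests

    return _with_nan(p, lambda q: multipletests(q, method="fdr_bh")[1])


def holm(p) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (NaN passed through)."""
    from statsmodels.stats.multitest import multipletests

    return _with_nan(p, lambda q: multipletests(q, method="holm")[1])
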