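"""Organismal phenotype models: starvation survival, offspring sex ratio,
and simple least-squares association tests.

Survival under starvation is modelled parametrically: the observed death
time (hours, uncensored) follows a logistic distribution whose location
is a linear function of genotype and line-within-genotype, with a common
scale — an accelerated-failure-time model on the raw time axis.  The
offspring sex ratio is a binomial logistic regression of female count
per vial on genotype and line, with a quasi-binomial scale estimate to
absorb vial-level overdispersion.  Post-hoc pairwise genotype contrasts
use Holm-corrected p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .anova import holm

__all__ = [
    "AFTFit",
    "fit_logistic_aft",
    "pairwise_contrasts",
    "SexRatioFit",
    "sex_ratio_glm",
    "ols_assoc",
]


def _genotype_line_design(
    df: pd.DataFrame, include_line: bool = True
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Cell-means genotype coding plus sum-to-zero line deviations.

    Returns (X, genotypes, lsmean_map) where ``lsmean_map @ params`` (over
    the location parameters) gives the genotype LS-means directly: with
    sum-to-zero line coding the genotype indicator's coefficient is the
    LS-mean over lines.
    """
    genos = sorted(df["genotype"].unique())
    cols = [(df["genotype"] == g).to_numpy(float) for g in genos]
    if include_line:
        for g in genos:
            sub = df["genotype"] == g
            lines = sorted(df.loc[sub, "line"].unique())
            counts = df.loc[sub, "line"].value_counts()
            usable = [l for l in lines if counts[l] >= 2]
            if len(usable) < len(lines):
                warnings.warn(
                    f"genotype {g!r}: lines with <2 observations pooled into "
                    "the genotype mean"
                )
            if len(usable) < 2:
                continue
            last = usable[-1]
            for l in usable[:-1]:
                col = (df["line"] == l).to_numpy(float) - (
                    df["line"] == last
                ).to_numpy(float)
                cols.append(col)
    X = np.column_stack(cols)
    lsmean_map = np.zeros((len(genos), X.shape[1]))
    lsmean_map[:, : len(genos)] = np.eye(len(genos))
    return X, genos, lsmean_map


@dataclass
class AFTFit:
    """Logistic accelerated-failure-time fit on raw death times."""

    lsmeans: pd.Series  # genotype locations, hours
    cov_lsmeans: pd.DataFrame
    scale: float
    loglik: float
    df_resid: float
    n: int
    converged: bool


def _logistic_nll_grad(params, X, y):
    b, log_s = params[:-1], params[-1]
    s = np.exp(log_s)
    z = (y - X @ b) / s
    nll = np.sum(z + 2.0 * np.logaddexp(0.0, -z) + log_s)
    u = 2.0 * expit(z) - 1.0  # d nll / dz
    grad_b = -(X.T @ u) / s
    grad_log_s = np.sum(1.0 - z * u)
    return nll, np.append(grad_b, grad_log_s)


def fit_logistic_aft(
    data: pd.DataFrame,
    include_line: bool = True,
    time_col: str = "time_h",
) -> AFTFit:
    """Maximum-likelihood logistic AFT: time = Genotype + Line(Genotype) + e.

    All deaths are treated as exactly observed.  Returns genotype
    LS-means (locations in hours) with their covariance from the inverse
    observed information, and the common logistic scale.
    """
    y = data[time_col].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("death times must be positive")
    X, genos, lsmean_map = _genotype_line_design(data, include_line)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("more parameters than observations")

    # start from group means and the moment estimate of the scale
    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    resid0 = y - X @ beta0
    s0 = max(np.std(resid0) * np.sqrt(3.0) / np.pi, 1e-3)
    x0 = np.append(beta0, np.log(s0))

    from scipy.optimize import minimize

    res = minimize(
        _logistic_nll_grad, x0, args=(X, y), jac=True, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    H = approx_hess(res.x, lambda p: _logistic_nll_grad(p, X, y)[0])
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov_b = cov_all[:k, :k]
    cov_ls = lsmean_map @ cov_b @ lsmean_map.T
    return AFTFit(
        lsmeans=pd.Series(res.x[:k] @ lsmean_map.T, index=genos, name="location_h"),
        cov_lsmeans=pd.DataFrame(cov_ls, index=genos, columns=genos),
        scale=float(np.exp(res.x[-1])),
        loglik=float(-res.fun),
        df_resid=float(n - (k + 1)),
        n=n,
        converged=bool(res.success),
    )


def pairwise_contrasts(
    lsmeans: pd.Series, cov: pd.DataFrame, df_resid: float
) -> pd.DataFrame:
    """All pairwise LS-mean differences with Holm-adjusted p-values."""
    rows = []
    for a, b in itertools.combinations(lsmeans.index, 2):
        diff = lsmeans[a] - lsmeans[b]
        se = np.sqrt(cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b])
        t = diff / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df_resid) if se > 0 else np.nan
        rows.append({"a": a, "b": b, "estimate": diff, "se": se, "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm(out["p"].to_numpy())
    return out


@dataclass
class SexRatioFit:
    """Quasi-binomial logistic regression of female offspring per vial."""

    lsmeans_logit: pd.Series
    cov_lsmeans: pd.DataFrame
    pct_female: pd.Series  # back-transformed LS-means, percent
    weighted_pct_female: pd.Series  # descriptive: per-genotype, progeny-weighted
    scale: float
    df_resid: float
    n_vials: int


def sex_ratio_glm(vials: pd.DataFrame, include_line: bool = True) -> SexRatioFit:
    """Fit female count ~ Genotype + Line(Genotype), binomial logit link.

    Vials with zero progeny are excluded with a warning.  The dispersion
    is estimated from Pearson residuals (quasi-binomial), absorbing
    vial-level clustering.  Also reports the descriptive per-genotype
    mean % female weighted by progeny per vial.
    """
    total = vials["n_female"] + vials["n_male"]
    if (total == 0).any():
        warnings.warn(f"excluding {(total == 0).sum()} vials with zero progeny")
        vials = vials[total > 0].reset_index(drop=True)
        total = vials["n_female"] + vials["n_male"]
    counts = vials.groupby("genotype").size()
    if (counts < 2).any():
        raise ValueError(
            f"need >=2 vials per genotype; short: {counts[counts < 2].index.tolist()}"
        )
    X, genos, lsmean_map = _genotype_line_design(vials, include_line)
    endog = vials[["n_female", "n_male"]].to_numpy(dtype=float)
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    # quasi-binomial dispersion from Pearson residuals; a perfect fit
    # (zero chi-square) degenerates to unit scale
    phi = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else 1.0
    if not np.isfinite(phi) or phi <= 0:
        phi = 1.0
    coefs = np.asarray(res.params)
    cov = lsmean_map @ (np.asarray(res.cov_params()) * phi) @ lsmean_map.T
    lsm = pd.Series(lsmean_map @ coefs, index=genos, name="logit_p_female")
    weighted = (
        vials.groupby("genotype")
        .apply(
            lambda d: 100.0 * d["n_female"].sum()
            / (d["n_female"].sum() + d["n_male"].sum()),
            include_groups=False,
        )
        .rename("weighted_pct_female")
    )
    return SexRatioFit(
        lsmeans_logit=lsm,
        cov_lsmeans=pd.DataFrame(cov, index=genos, columns=genos),
        pct_female=(100.0 * expit(lsm)).rename("pct_female"),
        weighted_pct_female=weighted,
        scale=phi,
        df_resid=float(res.df_resid),
        n_vials=len(vials),
    )


def ols_assoc(x, y) -> dict:
    """Simple least-squares regression of y on x with an F-test on the slope.

    Used for vial-level association tests (e.g. progeny count vs percent
    female, fecundity vs mean survival time).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "F": float(res.fvalue),
        "p": float(res.f_pvalue),
        "r2": float(res.rsquared),
        "n": int(x.size),
    }
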