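"""Redundancy, diversification, and epistasis among cluster paralogs.

Three quantities summarise how the paralogs divide labour on each
response (a transcript's expression or an organismal phenotype):

* **Diversification test** — ANOVA among the four single-paralog
  reinsertion genotypes (``Y = Genotype + Line(Genotype) + e``).  A
  significant genotype term means the paralogs act differently;
  otherwise their effects are considered redundant.
* **CoV** — the coefficient of variation (SD/mean, sample SD) of the
  four single-reinsertion LS-means; a continuous redundancy measure that
  does not depend on statistical power.  CoV below 0.2 is reported as
  "highly redundant".
* **Epistasis contrast** — the deviation of the full-cluster effect from
  the sum of the four single-paralog effects, every effect measured
  against the full knockout:

  ``(full - ko) - sum_p (single_p - ko)  =  full + 3*ko - sum_p single_p``

  Significant positive estimates are enhancing epistasis (the intact
  cluster does more than its parts), negative are suppressing.

Each gene lands in one of four quadrants by crossing the two FDR calls
at 0.05: redundant-additive, redundant-epistatic, diverse-additive,
diverse-epistatic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .anova import GeneFitBundle, bh_fdr, fit_gene_models
from .design import (
    DEFAULT_PARALOGS,
    FULL_INTACT,
    FULL_KNOCKOUT,
    single_reinsertion_genotypes,
)

__all__ = [
    "diversification_test",
    "cov_of_lsmeans",
    "epistasis_test",
    "epistasis_weights",
    "classify",
    "dissect_transcripts",
    "dissect_phenotype",
]

QUADRANTS = (
    "redundant-additive",
    "redundant-epistatic",
    "diverse-additive",
    "diverse-epistatic",
)

#: Reporting threshold under which a CoV is labelled highly redundant.
COV_REDUNDANT_THRESHOLD = 0.2


def diversification_test(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    sex: str,
    paralogs=DEFAULT_PARALOGS,
) -> tuple[pd.DataFrame, GeneFitBundle]:
    """Genotype F-test among the four single-reinsertion genotypes.

    Restricts to the given sex, fits ``Y = Genotype + Line(Genotype) + e``
    per gene, and tests the genotype term against the Line(Genotype) mean
    square.  Returns the per-gene test table and the fitted bundle (whose
    LS-means feed the CoV statistic).
    """
    singles = single_reinsertion_genotypes(tuple(paralogs))
    sub = meta[(meta["sex"] == sex) & meta["genotype"].isin(singles)]
    present = set(sub["genotype"])
    missing = [g for g in singles if g not in present]
    if missing:
        raise ValueError(f"missing single-reinsertion genotypes: {missing}")
    bundle = fit_gene_models(expr[sub["sample_id"].tolist()], sub)
    return bundle.genotype_ftest(), bundle


def cov_of_lsmeans(lsmeans, ddof: int = 1) -> float:
    """SD/mean of single-reinsertion LS-means (sample SD by default).

    Scale-invariant under multiplication by a positive constant.  When
    the mean is not positive (possible on a log scale) the CoV is
    undefined and NaN is returned with a warning rather than a silently
    wrong value.
    """
    x = np.asarray(lsmeans, dtype=float)
    mean = x.mean()
    if mean <= 0:
        warnings.warn(
            f"CoV undefined: mean of LS-means is {mean:.4g} <= 0 "
            "(consider the linear scale)"
        )
        return float("nan")
    return float(x.std(ddof=ddof) / mean)


def _cov_vector(lsmeans: np.ndarray, ddof: int = 1) -> np.ndarray:
    mean = lsmeans.mean(axis=1)
    sd = lsmeans.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, sd / mean, np.nan)


def epistasis_weights(
    sex: str, paralogs=DEFAULT_PARALOGS
) -> dict[tuple[str, str], float]:
    """Contrast weights of the epistasis test: +1 intact, +3 knockout,
    -1 on each single reinsertion (all within one sex)."""
    weights = {(FULL_INTACT, sex): 1.0, (FULL_KNOCKOUT, sex): 3.0}
    for g in single_reinsertion_genotypes(tuple(paralogs)):
        weights[(g, sex)] = -1.0
    return weights


def epistasis_test(
    bundle: GeneFitBundle, sex: str, paralogs=DEFAULT_PARALOGS
) -> pd.DataFrame:
    """Deviation-from-additivity contrast for every gene, one sex."""
    weights = epistasis_weights(sex, paralogs)
    missing = [c for c in weights if c not in set(bundle.cells)]
    if missing:
        raise ValueError(f"epistasis test needs absent cells: {missing}")
    return bundle.contrast(weights, label="epistasis")


def classify(
    divers_fdr: float, epi_fdr: float, epi_estimate: float, threshold: float = 0.05
) -> tuple[str, str]:
    """Quadrant and epistasis direction from the two FDR calls."""
    if np.isnan(divers_fdr) or np.isnan(epi_fdr):
        return "NA", "none"
    diverse = divers_fdr < threshold
    epistatic = epi_fdr < threshold
    quadrant = ("diverse" if diverse else "redundant") + "-" + (
        "epistatic" if epistatic else "additive"
    )
    direction = "none"
    if epistatic and not np.isnan(epi_estimate) and epi_estimate != 0:
        direction = "enhancing" if epi_estimate > 0 else "suppressing"
    return quadrant, direction


def dissect_transcripts(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    sexes=("F", "M"),
    genes: list[str] | None = None,
    paralogs=DEFAULT_PARALOGS,
    fdr_threshold: float = 0.05,
    cov_scale: str = "linear",
    full_bundle: GeneFitBundle | None = None,
) -> pd.DataFrame:
    """Full dissection table: diversification p/FDR, CoV, epistasis
    estimate/p/FDR, quadrant and direction, per gene and sex.

    ``genes`` restricts the analysis (typically to transcriptional-niche
    members); FDR is computed within the analysed set.  ``cov_scale``
    chooses whether the CoV is taken on the model (log) scale or after
    back-transforming LS-means to the linear scale (default: means are
    then positive and the CoV well defined).
    """
    if cov_scale not in ("linear", "model"):
        raise ValueError("cov_scale must be 'linear' or 'model'")
    if genes is not None:
        expr = expr.loc[[g for g in genes if g in expr.index]]
        if expr.shape[0] == 0:
            raise ValueError("no analysable genes after restriction")
    if full_bundle is None:
        full_bundle = fit_gene_models(expr, meta)
    rows = []
    for sex in sexes:
        div, div_bundle = diversification_test(expr, meta, sex, paralogs)
        singles = single_reinsertion_genotypes(tuple(paralogs))
        lsm = div_bundle.lsmean_frame()
        lsm = lsm.loc[expr.index, [(g, sex) for g in singles]].to_numpy()
        if cov_scale == "linear":
            lsm = np.exp2(lsm)
        cov = _cov_vector(lsm)
        epi = epistasis_test(full_bundle, sex, paralogs).loc[expr.index]
        table = pd.DataFrame(
            {
                "gene": expr.index,
                "sex": sex,
                "divers_p": div.loc[expr.index, "p"].to_numpy(),
                "divers_fdr": bh_fdr(div.loc[expr.index, "p"].to_numpy()),
                "cov": cov,
                "epi_estimate": epi["estimate"].to_numpy(),
                "epi_se": epi["se"].to_numpy(),
                "epi_p": epi["p"].to_numpy(),
                "epi_fdr": bh_fdr(epi["p"].to_numpy()),
            }
        )
        rows.append(table)
    out = pd.concat(rows, ignore_index=True)
    quad_dir = [
        classify(d, e, est, fdr_threshold)
        for d, e, est in zip(out["divers_fdr"], out["epi_fdr"], out["epi_estimate"])
    ]
    out["quadrant"] = [q for q, _ in quad_dir]
    out["epistasis_direction"] = [d for _, d in quad_dir]
    out["highly_redundant"] = out["cov"] < COV_REDUNDANT_THRESHOLD
    return out


def dissect_phenotype(
    lsmeans: pd.Series,
    cov: pd.DataFrame,
    df_resid: float,
    paralogs=DEFAULT_PARALOGS,
    fdr_threshold: float = 0.05,
) -> dict:
    """Apply the dissection contrasts to genotype-level phenotype fits.

    ``lsmeans`` is indexed by genotype (on the model's response scale,
    e.g. hours for survival or logits for sex ratio) with coefficient
    covariance ``cov``.  Returns the epistasis estimate/SE/p, the Wald
    diversification test among the four single reinsertions, and the CoV
    of their LS-means.
    """
    singles = single_reinsertion_genotypes(tuple(paralogs))
    needed = [FULL_INTACT, FULL_KNOCKOUT, *singles]
    missing = [g for g in needed if g not in lsmeans.index]
    if missing:
        raise ValueError(f"phenotype fit lacks genotypes: {missing}")
    V = cov.loc[needed, needed].to_numpy()
    m = lsmeans.loc[needed].to_numpy()

    w = np.array([1.0, 3.0, -1.0, -1.0, -1.0, -1.0])
    est = float(w @ m)
    se = float(np.sqrt(w @ V @ w))
    t = est / se if se > 0 else np.nan
    epi_p = float(2 * stats.t.sf(abs(t), df_resid)) if se > 0 else float("nan")

    # Wald F: equality of the four single-reinsertion LS-means
    C = np.zeros((3, len(needed)))
    for i in range(3):
        C[i, 2 + i] = 1.0
        C[i, 2 + i + 1] = -1.0
    d = C @ m
    Vc = C @ V @ C.T
    try:
        f = float(d @ np.linalg.solve(Vc, d) / C.shape[0])
        div_p = float(stats.f.sf(f, C.shape[0], df_resid))
    except np.linalg.LinAlgError:
        f, div_p = float("nan"), float("nan")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cov_stat = cov_of_lsmeans(lsmeans.loc[singles].to_numpy())
    quadrant, direction = classify(div_p, epi_p, est, fdr_threshold)
    return {
        "epi_estimate": est,
        "epi_se": se,
        "epi_p": epi_p,
        "divers_F": f,
        "divers_p": div_p,
        "cov": cov_stat,
        "quadrant": quadrant,
        "epistasis_direction": direction,
    }
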