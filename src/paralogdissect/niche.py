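"""Transcriptional niches: DEG sets per paralog and for the full cluster.

A paralog's transcriptional niche is the set of genes differentially
expressed between the genotype in which only that paralog is functional
and the full-knockout genotype, per sex; the cluster niche contrasts the
fully intact genotype against the knockout.  Membership is called at a
BH-FDR threshold applied per niche per sex across genes, with direction
"up" meaning higher expression in the presence of the functional
paralog(s).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .anova import GeneFitBundle, bh_fdr
from .design import (
    DEFAULT_PARALOGS,
    FULL_INTACT,
    FULL_KNOCKOUT,
    single_reinsertion_genotypes,
)

__all__ = ["niche_contrasts", "call_niches", "niche_summary", "niche_genotypes"]

CLUSTER_NICHE = "cluster"


def niche_genotypes(paralogs=DEFAULT_PARALOGS) -> dict[str, str]:
    """Map niche name -> genotype contrasted against the full knockout."""
    singles = single_reinsertion_genotypes(tuple(paralogs))
    mapping = dict(zip(paralogs, singles))
    mapping[CLUSTER_NICHE] = FULL_INTACT
    return mapping


def niche_contrasts(
    bundle: GeneFitBundle,
    sex: str,
    paralogs=DEFAULT_PARALOGS,
    knockout: str = FULL_KNOCKOUT,
    include_cd: bool = False,
) -> pd.DataFrame:
    """LS-means contrasts defining each niche for one sex.

    For every niche, estimate = LSmean(niche genotype, sex) -
    LSmean(knockout, sex).  Returns a long DataFrame (gene, niche,
    estimate, se, df, t, p); niches whose genotype is absent from the fit
    are skipped with a warning.

    CD-allele genotypes are excluded by default (the CD allele's
    functional status is a finding, not an assumption); ``include_cd``
    adds the CD-based contrasts: the b-CD genotype against the knockout,
    and the c reinsertion within the b-CD background.
    """
    cells = set(bundle.cells)
    if (knockout, sex) not in cells:
        raise ValueError(f"knockout genotype cell ({knockout!r}, {sex!r}) absent")
    pairs = {
        niche: (genotype, knockout)
        for niche, genotype in niche_genotypes(paralogs).items()
    }
    if include_cd:
        pairs["b_cd"] = ("-CD--", knockout)
        pairs["c_in_cd_background"] = ("-CD+-", "-CD--")
    out = []
    for niche, (genotype, baseline) in pairs.items():
        if (genotype, sex) not in cells or (baseline, sex) not in cells:
            warnings.warn(
                f"genotype {genotype!r} absent for sex {sex!r}; niche "
                f"{niche!r} skipped"
            )
            continue
        tab = bundle.contrast(
            {(genotype, sex): 1.0, (baseline, sex): -1.0}, label=niche
        ).reset_index()
        tab.insert(1, "niche", niche)
        tab.insert(2, "sex", sex)
        out.append(tab.drop(columns="label"))
    return pd.concat(out, ignore_index=True)


def call_niches(contrasts: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Call niche membership from contrast p-values.

    FDR is computed per (niche, sex) across genes; a gene is a member
    when FDR < threshold, with direction the sign of the estimate.
    """
    out = contrasts.copy()
    out["fdr"] = (
        out.groupby(["niche", "sex"])["p"].transform(lambda p: bh_fdr(p.to_numpy()))
    )
    out["member"] = out["fdr"] < fdr_threshold
    out["direction"] = "none"
    out.loc[out["member"] & (out["estimate"] > 0), "direction"] = "up"
    out.loc[out["member"] & (out["estimate"] < 0), "direction"] = "down"
    return out


def niche_summary(niches: pd.DataFrame) -> pd.DataFrame:
    """Member counts and % up-regulated per niche and sex."""
    rows = []
    for (niche, sex), grp in niches.groupby(["niche", "sex"]):
        members = grp[grp["member"]]
        n = len(members)
        pct_up = 100.0 * (members["estimate"] > 0).mean() if n else float("nan")
        rows.append({"niche": niche, "sex": sex, "n_members": n, "pct_up": pct_up})
    return pd.DataFrame(rows)


def niche_gene_set(niches: pd.DataFrame, sex: str | None = None) -> list[str]:
    """Genes belonging to at least one niche (optionally for one sex)."""
    sub = niches[niches["member"]]
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    return sorted(sub["gene"].unique())
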