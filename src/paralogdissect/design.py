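"""Experimental design for deletion-reinsertion paralog dissection.

A cluster of tandem paralogs is deleted and reinserted in engineered
versions in which each paralog is either functional ("+"), inactivated by
premature stop codons ("-"), or carries conserved-residue substitutions
("CD").  A genotype is written as one allele symbol per paralog, e.g.
``-CD+-`` means paralog 1 knocked out, paralog 2 carrying the CD allele,
paralog 3 functional, paralog 4 knocked out.

The default design is the four-paralog cluster layout: a fully intact
genotype, a full knockout, the four single-paralog reinsertions, and two
CD-allele genotypes, each represented by up to two independently derived
lines, with both sexes and replicate pools per line.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ALLELE_SYMBOLS",
    "DEFAULT_PARALOGS",
    "DEFAULT_GENOTYPES",
    "FULL_INTACT",
    "FULL_KNOCKOUT",
    "DesignConfig",
    "parse_genotype",
    "functional_mask",
    "single_reinsertion_genotypes",
    "simulate_design",
    "validate_metadata",
    "has_line_replication",
]

#: Recognised allele symbols.  "+" = functional, "-" = premature stop codons
#: (knockout), "CD" = conserved residues substituted.
ALLELE_SYMBOLS = ("+", "-", "CD")

DEFAULT_PARALOGS = ("a", "b", "c", "d")

FULL_INTACT = "++++"
FULL_KNOCKOUT = "----"

#: The eight cluster genotypes of the reference design: intact, knockout,
#: the four single-paralog reinsertions, and the two CD-allele genotypes.
DEFAULT_GENOTYPES = (
    "++++",
    "----",
    "+---",
    "-+--",
    "--+-",
    "---+",
    "-CD+-",
    "-CD--",
)

SEXES = ("F", "M")

# Unicode minus / dashes occasionally used in genotype strings.
_DASH_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def _normalise(genotype: str) -> str:
    for bad, good in _DASH_VARIANTS.items():
        genotype = genotype.replace(bad, good)
    return genotype


def parse_genotype(genotype: str, n_paralogs: int = 4) -> tuple[str, ...]:
    """Split an allele string into per-paralog allele calls.

    ``"-CD+-"`` -> ``("-", "CD", "+", "-")``.  Unicode minus signs are
    accepted and normalised to ASCII ``-``.

    Raises
    ------
    ValueError
        If an unknown symbol occurs or the number of alleles does not
        match ``n_paralogs``.
    """
    s = _normalise(str(genotype))
    alleles: list[str] = []
    i = 0
    while i < len(s):
        if s[i] in ("+", "-"):
            alleles.append(s[i])
            i += 1
        elif s[i : i + 2] == "CD":
            alleles.append("CD")
            i += 2
        else:
            raise ValueError(
                f"unknown allele symbol at position {i} in genotype {genotype!r}; "
                f"expected one of {ALLELE_SYMBOLS}"
            )
    if len(alleles) != n_paralogs:
        raise ValueError(
            f"genotype {genotype!r} has {len(alleles)} alleles, expected {n_paralogs}"
        )
    return tuple(alleles)


def functional_mask(
    genotype: str, n_paralogs: int = 4, cd_functional: bool = False
) -> tuple[bool, ...]:
    """Which paralogs are functional in a genotype.

    The CD allele is treated as non-functional unless ``cd_functional``.
    """
    alleles = parse_genotype(genotype, n_paralogs)
    return tuple(a == "+" or (a == "CD" and cd_functional) for a in alleles)


def single_reinsertion_genotypes(
    paralogs: tuple[str, ...] = DEFAULT_PARALOGS,
) -> list[str]:
    """Genotypes with exactly one functional paralog, in paralog order."""
    n = len(paralogs)
    return ["".join("+" if j == i else "-" for j in range(n)) for i in range(n)]


@dataclass
class DesignConfig:
    """Factor levels of a deletion-reinsertion experiment.

    Parameters
    ----------
    paralog_names
        Identifiers of the clustered paralogs, in genomic order.
    genotypes
        Allele strings over ``{+, -, CD}``, one symbol group per paralog.
    sexes
        Sex levels; both sexes by default.
    lines_per_genotype
        Number of independently derived lines per genotype.  With a single
        line the nested Line(Genotype) term has zero degrees of freedom and
        downstream models drop it.
    replicates_per_cell
        Replicate pools per genotype x sex x line cell.
    """

    paralog_names: tuple[str, ...] = DEFAULT_PARALOGS
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    sexes: tuple[str, ...] = SEXES
    lines_per_genotype: int = 2
    replicates_per_cell: int = 3

    def __post_init__(self) -> None:
        self.genotypes = tuple(_normalise(g) for g in self.genotypes)
        if len(set(self.genotypes)) != len(self.genotypes):
            dups = sorted(
                g for g in set(self.genotypes) if list(self.genotypes).count(g) > 1
            )
            raise ValueError(f"duplicate genotype strings in design: {dups}")
        if self.lines_per_genotype < 1:
            raise ValueError("lines_per_genotype must be >= 1")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        n = len(self.paralog_names)
        for g in self.genotypes:
            parse_genotype(g, n)  # raises on malformed strings

    @property
    def n_samples(self) -> int:
        return (
            len(self.genotypes)
            * len(self.sexes)
            * self.lines_per_genotype
            * self.replicates_per_cell
        )


def simulate_design(config: DesignConfig | None = None) -> pd.DataFrame:
    """Enumerate sample metadata for a design.

    Returns a DataFrame with one row per genotype x sex x line x replicate
    and columns ``sample_id, genotype, sex, line, replicate``.  Line
    identifiers embed the genotype (nested coding): a line label is only
    meaningful within its genotype.

    The frame's ``attrs['has_line_replication']`` flags whether the
    Line(Genotype) term has any degrees of freedom.
    """
    config = config or DesignConfig()
    rows = []
    for g, s, l, r in itertools.product(
        config.genotypes,
        config.sexes,
        range(1, config.lines_per_genotype + 1),
        range(1, config.replicates_per_cell + 1),
    ):
        line = f"{g}_L{l}"
        rows.append(
            {
                "sample_id": f"{g}_{s}_L{l}_R{r}",
                "genotype": g,
                "sex": s,
                "line": line,
                "replicate": r,
            }
        )
    meta = pd.DataFrame(rows)
    meta.attrs["has_line_replication"] = config.lines_per_genotype > 1
    meta.attrs["paralog_names"] = tuple(config.paralog_names)
    validate_metadata(meta, n_paralogs=len(config.paralog_names))
    return meta


def validate_metadata(meta: pd.DataFrame, n_paralogs: int = 4) -> pd.DataFrame:
    """Validate a sample metadata table, parsing every genotype string.

    Raises ``ValueError`` naming the offending row on malformed genotypes,
    duplicate sample ids, or missing columns.
    """
    required = {"sample_id", "genotype", "sex", "line"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    for idx, g in meta["genotype"].items():
        try:
            parse_genotype(g, n_paralogs)
        except ValueError as exc:
            raise ValueError(f"metadata row {idx}: {exc}") from exc
    return meta


def has_line_replication(meta: pd.DataFrame) -> bool:
    """True if at least one genotype has more than one line."""
    return bool((meta.groupby("genotype")["line"].nunique() > 1).any())
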