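"""Tabular input/output and pipeline configuration.

Canonical formats are TSV: counts as genes x samples with a header row of
sample ids, gene lengths and metadata as two-or-more-column tables.
MatrixMarket (.mtx) counts are accepted with sidecar row/column name
files.  Configuration round-trips through YAML/JSON losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .design import validate_metadata

__all__ = [
    "read_counts",
    "read_lengths",
    "read_metadata",
    "write_table",
    "PipelineConfig",
]


def read_counts(
    path: str | Path,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a gene x sample integer count matrix (TSV, or MTX + names)."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if genes_path is None or samples_path is None:
            raise ValueError("MTX counts need sidecar gene and sample name files")
        mat = mmread(path).toarray()
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in counts: {dups[:5]}")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in counts")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def read_lengths(path: str | Path) -> pd.Series:
    """Read per-gene lengths (bp) from a two-column TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    series = table.iloc[:, 0].astype(float)
    if series.index.duplicated().any():
        raise ValueError("duplicate gene ids in lengths table")
    if (series <= 0).any():
        bad = series.index[series <= 0].tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:5]}")
    series.name = "length_bp"
    return series


def read_metadata(path: str | Path, n_paralogs: int = 4) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    Requires columns sample_id, genotype, sex, line; genotype strings are
    parsed into per-paralog allele calls and malformed rows are reported
    with their row number.
    """
    meta = pd.read_csv(path, sep="\t")
    return validate_metadata(meta, n_paralogs=n_paralogs)


def check_counts_metadata(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every count column must have a metadata row."""
    known = set(meta["sample_id"])
    unknown = [s for s in counts.columns if s not in known]
    if unknown:
        raise ValueError(f"samples in counts absent from metadata: {unknown[:5]}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Thresholds default to the analysis conventions of the framework: FDR
    0.05 throughout, CoV 0.2 as the highly-redundant reporting label, and
    a configurable hard correlation threshold for network edge lists.
    """

    counts: str | None = None
    lengths: str | None = None
    metadata: str | None = None
    outdir: str = "results"
    fdr_threshold: float = 0.05
    cov_redundant_threshold: float = 0.2
    network_hard_threshold: float = 0.7
    network_preset: str = "dissection"
    min_nonzero_fraction: float = 0.25
    min_median_count: float = 2.0
    log_offset: float = 0.5
    cov_scale: str = "linear"
    restrict_dissection_to_niche: bool = True
    run_qc: bool = True
    seed: int = 0
    # synthetic-experiment settings used when no counts path is given
    simulate: bool = False
    n_genes: int = 200
    lines_per_genotype: int = 2
    replicates_per_cell: int = 3

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "cov_redundant_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.network_hard_threshold <= 1.0:
            raise ValueError("network_hard_threshold must be in [0, 1]")
        if self.cov_scale not in ("linear", "model"):
            raise ValueError("cov_scale must be 'linear' or 'model'")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
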