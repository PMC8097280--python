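"""End-to-end driver: filter -> normalize -> QC -> fit -> niches ->
dissection -> network, with a manifest for reproducibility."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import fit_gene_models
from .design import DesignConfig, simulate_design
from .dissection import dissect_transcripts
from .io import (
    PipelineConfig,
    check_counts_metadata,
    read_counts,
    read_lengths,
    read_metadata,
    write_table,
)
from .network import NETWORK_PRESETS, bicor_matrix, build_edges, call_hubs
from .niche import call_niches, niche_contrasts, niche_gene_set, niche_summary
from .preprocess import filter_genes, flag_outlier_samples, getmm_normalize
from .simulate import CountTruthConfig, simulate_counts

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _load_inputs(config: PipelineConfig):
    if config.simulate or config.counts is None:
        rng = np.random.default_rng(config.seed)
        meta = simulate_design(
            DesignConfig(
                lines_per_genotype=config.lines_per_genotype,
                replicates_per_cell=config.replicates_per_cell,
            )
        )
        n = config.n_genes
        beta = np.zeros((n, 4))
        affected = rng.choice(n, size=max(n // 10, 1), replace=False)
        # each affected gene responds to one random paralog, moderate size
        beta[affected, rng.integers(0, 4, size=len(affected))] = rng.normal(
            1.2, 0.3, size=len(affected)
        )
        truth_cfg = CountTruthConfig(
            n_genes=n, paralog_effects=beta, seed=config.seed
        )
        counts, lengths, truth = simulate_counts(meta, truth_cfg)
        return counts, lengths, meta, truth
    counts = read_counts(config.counts)
    lengths = read_lengths(config.lengths)
    meta = read_metadata(config.metadata)
    check_counts_metadata(counts, meta)
    return counts, lengths, meta, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write TSV outputs plus a JSON manifest.

    Rerunning with identical inputs and seed reproduces every table
    bit-for-bit.  Returns the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "fdr_threshold": config.fdr_threshold,
        "stages": {},
    }

    counts, lengths, meta, truth = _load_inputs(config)
    if truth is not None:
        write_table(truth, outdir / "simulation_truth.tsv", index=False)
        write_table(counts, outdir / "counts.tsv")
        write_table(lengths.to_frame(), outdir / "gene_lengths.tsv")
        write_table(meta, outdir / "metadata.tsv", index=False)
    manifest["stages"]["input"] = {
        "genes": int(counts.shape[0]),
        "samples": int(counts.shape[1]),
    }

    filtered = filter_genes(
        counts, config.min_nonzero_fraction, config.min_median_count
    )
    manifest["stages"]["filter"] = {
        "genes_in": int(counts.shape[0]),
        "genes_out": int(filtered.shape[0]),
    }

    expr = getmm_normalize(filtered, lengths, log2=True, offset=config.log_offset)
    write_table(expr, outdir / "expression_log2_getmm.tsv")

    flagged: list[str] = []
    if config.run_qc:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flagged = flag_outlier_samples(
                expr, meta.set_index("sample_id").loc[expr.columns, "sex"]
            )
        if flagged:
            # never empty a genotype x sex cell: keep flags that would
            kept = meta[~meta["sample_id"].isin(flagged)]
            before = meta.groupby(["genotype", "sex"]).size()
            after = kept.groupby(["genotype", "sex"]).size().reindex(
                before.index, fill_value=0
            )
            if (after == 0).any():
                emptied = [tuple(c) for c in after.index[after == 0]]
                logger.warning(
                    "QC flags would empty design cells %s; keeping those samples",
                    emptied,
                )
                protect = meta["genotype"].combine(
                    meta["sex"], lambda g, s: (g, s) in emptied
                )
                flagged = [
                    s
                    for s in flagged
                    if s not in set(meta.loc[protect, "sample_id"])
                ]
            expr = expr.drop(columns=flagged)
            meta = meta[~meta["sample_id"].isin(flagged)]
    manifest["stages"]["qc"] = {"flagged_samples": flagged}

    bundle = fit_gene_models(expr, meta)
    sexes = sorted(meta["sex"].unique())
    contrasts = pd.concat(
        [niche_contrasts(bundle, sex) for sex in sexes], ignore_index=True
    )
    niches = call_niches(contrasts, config.fdr_threshold)
    write_table(niches, outdir / "niche_table.tsv", index=False)
    summary = niche_summary(niches)
    write_table(summary, outdir / "niche_summary.tsv", index=False)
    manifest["stages"]["niches"] = {
        "n_member_calls": int(niches["member"].sum())
    }

    genes = niche_gene_set(niches) if config.restrict_dissection_to_niche else None
    if genes is not None and len(genes) == 0:
        logger.info("no niche members; dissecting all genes instead")
        genes = None
    dissection = dissect_transcripts(
        expr,
        meta,
        sexes=sexes,
        genes=genes,
        fdr_threshold=config.fdr_threshold,
        cov_scale=config.cov_scale,
    )
    dissection["minus_log10_divers_p"] = -np.log10(dissection["divers_p"])
    dissection["minus_log10_epi_p"] = -np.log10(dissection["epi_p"])
    write_table(dissection, outdir / "dissection_table.tsv", index=False)
    manifest["stages"]["dissection"] = {
        "genes": int(dissection["gene"].nunique()),
        "quadrants": dissection["quadrant"].value_counts().to_dict(),
    }

    preset = NETWORK_PRESETS[config.network_preset]
    net_meta = meta[(meta["sex"] == "M") & meta["genotype"].isin(preset)]
    net_genes = dissection["gene"].unique().tolist()
    if len(net_meta) >= 4 and len(net_genes) >= 2:
        corr = bicor_matrix(expr.loc[net_genes, net_meta["sample_id"].tolist()])
        edges = build_edges(corr, config.network_hard_threshold)
        hubs = call_hubs(edges)
        write_table(edges.edges, outdir / "network_edges.tsv", index=False)
        write_table(edges.nodes, outdir / "network_nodes.tsv", index=False)
        manifest["stages"]["network"] = {
            "nodes": int(len(edges.nodes)),
            "edges": int(len(edges.edges)),
            "hubs": hubs,
        }
    else:
        manifest["stages"]["network"] = {"skipped": "too few samples or genes"}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
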