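"""Gene-level exonic methylation aggregates and hypermethylated-position counts.

A gene's methylation level in one sample is the read-weighted level over its
exonic, depth-passing cytosine sites:

    level_pct = 100 * sum(methylated reads) / sum(total reads)

The read-weighted form is robust to depth heterogeneity across sites; the
unweighted mean of site levels is available for sensitivity analysis. A gene
is *methylated* in a sample when at least one of its exonic sites is
methylated (>= 1 methylated read by default).

Genes whose exons overlap another gene's exons double-count the shared sites
in both gene records: each record is self-contained.
"""

from __future__ import annotations

import pandas as pd

from .sites import FilterConfig

__all__ = ["aggregate_genes", "count_methylated_genes", "chrom_context_counts"]

GENE_RECORD_COLUMNS = [
    "gene_id",
    "sample_id",
    "n_exonic_sites",
    "meth_reads_sum",
    "total_reads_sum",
    "level_pct",
    "n_cpg",
    "n_chg",
    "n_chh",
    "n_hyper_positions",
    "is_methylated_gene",
]


def aggregate_genes(
    classified: pd.DataFrame,
    sample_id: str,
    cfg: FilterConfig | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """One record per gene with >= 1 exonic depth-passing site.

    ``classified`` is the output of :func:`methkit.sites.classify_sites`
    (already depth-filtered, with ``region``/``gene_id``/``level_pct``/
    ``intensity`` columns). With ``weighted=False`` the gene level is the
    unweighted mean of site levels instead of the read-weighted level.
    """
    cfg = cfg or FilterConfig()
    ex = classified.loc[classified["region"] == "exonic"]
    if ex.empty:
        return pd.DataFrame(columns=GENE_RECORD_COLUMNS)
    meth_site = (ex["meth"] >= cfg.min_meth_reads) & (
        ex["level_pct"] >= cfg.min_meth_level_pct
    )
    tmp = pd.DataFrame(
        {
            "gene_id": ex["gene_id"].to_numpy(),
            "meth": ex["meth"].to_numpy(),
            "total": (ex["meth"] + ex["unmeth"]).to_numpy(),
            "level": ex["level_pct"].to_numpy(),
            "is_cpg": (ex["context"] == "CpG").to_numpy(),
            "is_chg": (ex["context"] == "CHG").to_numpy(),
            "is_chh": (ex["context"] == "CHH").to_numpy(),
            "is_hyper": (ex["intensity"] == "hypermethylated").to_numpy(),
            "is_meth": meth_site.to_numpy(),
        }
    )
    g = tmp.groupby("gene_id", sort=True)
    agg = g.agg(
        n_exonic_sites=("meth", "size"),
        meth_reads_sum=("meth", "sum"),
        total_reads_sum=("total", "sum"),
        mean_site_level=("level", "mean"),
        n_cpg=("is_cpg", "sum"),
        n_chg=("is_chg", "sum"),
        n_chh=("is_chh", "sum"),
        n_hyper_positions=("is_hyper", "sum"),
        is_methylated_gene=("is_meth", "any"),
    ).reset_index()
    if weighted:
        agg["level_pct"] = 100.0 * agg["meth_reads_sum"] / agg["total_reads_sum"]
    else:
        agg["level_pct"] = agg["mean_site_level"]
    agg["sample_id"] = sample_id
    return agg[GENE_RECORD_COLUMNS]


def count_methylated_genes(records: pd.DataFrame) -> int:
    """Number of genes flagged methylated (>= 1 methylated exonic site)."""
    if records.empty:
        return 0
    return int(records["is_methylated_gene"].sum())


def chrom_context_counts(
    classified: pd.DataFrame, sample_id: str, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Hypermethylated exonic positions per chromosome x context.

    These counts (one row per chromosome per context, zero-filled) are the
    observational units of the downstream ANOVA across condition x context
    groups, with chromosomes as replicates.
    """
    cfg = cfg or FilterConfig()
    mask = (classified["region"] == "exonic") & (
        classified["level_pct"] >= cfg.hyper_min_pct
    )
    sub = classified.loc[mask]
    chroms = sorted(classified["chrom"].unique())
    contexts = ["CpG", "CHG", "CHH"]
    counts = (
        sub.groupby(["chrom", "context"], sort=True).size().rename("n_hyper_exonic_positions")
    )
    full = pd.MultiIndex.from_product([chroms, contexts], names=["chrom", "context"])
    out = counts.reindex(full, fill_value=0).reset_index()
    out.insert(0, "sample_id", sample_id)
    return out
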