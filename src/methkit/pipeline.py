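"""One-shot orchestration: simulate -> classify -> aggregate -> contrast -> patterns.

A run is described by a single :class:`RunConfig` (loadable from a YAML
file). Inputs are either simulated into the output directory or read from
existing files (reference FASTA, GFF3 annotation, sample sheet of cytosine
reports). Every stage writes TSV outputs under the output directory and the
run ends with a JSON manifest recording the config, per-file SHA-256
checksums, timestamps and the warning count — re-running with the same
config and inputs reproduces identical checksums for all deterministic
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .contrasts import contrast_family
from .genes import aggregate_genes, chrom_context_counts, count_methylated_genes
from .io import (
    MethkitError,
    read_cytosine_report,
    read_gff3,
    read_sample_sheet,
    write_table,
)
from .patterns import build_matrix, cluster_common_hyper, overlap_counts, pca, top_k_variable
from .simulate import SimConfig, simulate_study
from .sites import FilterConfig, classify_sites, summarize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline"]


@dataclass
class ContrastConfig:
    reference_condition: str
    alpha: float = 0.05
    dmg_delta_threshold: float = 10.0
    zero_method: str = "wilcox"


@dataclass
class PatternConfig:
    top_k: int = 500
    scale: bool = False
    hyper_min_pct: float = 70.0


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimConfig | None = None
    reference: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    # raw filter parameters; validated (not thrown) by validate_config
    filter: dict[str, Any] = field(default_factory=dict)
    contrasts: list[ContrastConfig] = field(default_factory=list)
    patterns: PatternConfig = field(default_factory=PatternConfig)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(**self.filter)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        sim = raw.get("simulate")
        if sim is not None:
            if "seed" not in sim:
                sim = {**sim, "seed": raw.get("seed", 0)}
            if "exons_per_gene" in sim:
                sim["exons_per_gene"] = tuple(sim["exons_per_gene"])
            if "gene_length" in sim:
                sim["gene_length"] = tuple(sim["gene_length"])
            sim = SimConfig(**sim)
        return cls(
            output_dir=raw.get("output_dir", "methkit_run"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            simulate=sim,
            reference=raw.get("reference"),
            annotation=raw.get("annotation"),
            sample_sheet=raw.get("sample_sheet"),
            filter=dict(raw.get("filter", {})),
            contrasts=[ContrastConfig(**c) for c in raw.get("contrasts", [])],
            patterns=PatternConfig(**raw.get("patterns", {})),
        )


@dataclass
class RunManifest:
    version: str
    config: dict[str, Any]
    checksums: dict[str, str]
    started: str
    finished: str
    n_warnings: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def validate_config(cfg: RunConfig) -> list[str]:
    """All invariant violations at once (empty list = valid)."""
    problems: list[str] = []
    if cfg.simulate is None:
        for name in ("annotation", "sample_sheet"):
            p = getattr(cfg, name)
            if p is None:
                problems.append(f"{name} path required when not simulating")
            elif not os.path.exists(p):
                problems.append(f"{name} path does not exist: {p}")
    for c in cfg.contrasts:
        if not 0 < c.alpha < 1:
            problems.append(f"contrast alpha {c.alpha} outside (0, 1)")
        if c.dmg_delta_threshold < 0:
            problems.append(f"dmg_delta_threshold {c.dmg_delta_threshold} negative")
    try:
        cfg.filter_config()
    except (MethkitError, TypeError) as exc:
        problems.append(str(exc))
    if cfg.patterns.top_k < 1:
        problems.append("patterns.top_k must be >= 1")
    if cfg.simulate is not None:
        conditions = set(cfg.simulate.resolved_condition_effects())
        for c in cfg.contrasts:
            if c.reference_condition not in conditions:
                problems.append(
                    f"reference condition {c.reference_condition!r} absent from simulated conditions"
                )
    if cfg.simulate is None and cfg.sample_sheet and os.path.exists(cfg.sample_sheet):
        try:
            sheet = read_sample_sheet(cfg.sample_sheet)
            conditions = set(sheet.frame["condition"])
            for c in cfg.contrasts:
                if c.reference_condition not in conditions:
                    problems.append(
                        f"reference condition {c.reference_condition!r} absent from sample sheet"
                    )
        except MethkitError as exc:
            problems.append(str(exc))
    return problems


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record) -> None:
        self.count += 1


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in dependency order and write the manifest last.

    A failure inside one contrast is logged and does not abort the others.
    Raises :class:`MethkitError` listing every validation problem before
    any computation when the config is invalid.
    """
    problems = validate_config(cfg)
    if problems:
        raise MethkitError("invalid configuration:\n- " + "\n- ".join(problems))

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    fcfg = cfg.filter_config()
    os.makedirs(cfg.output_dir, exist_ok=True)
    counter = _WarningCounter()
    logging.getLogger("methkit").addHandler(counter)
    outputs: list[str] = []

    def emit(frame: pd.DataFrame, name: str, precision: int = 4) -> None:
        path = os.path.join(cfg.output_dir, name)
        write_table(frame, path, precision)
        outputs.append(path)

    try:
        # --- inputs -------------------------------------------------------
        if cfg.simulate is not None:
            sim_dir = os.path.join(cfg.output_dir, "sim")
            sheet, _ = simulate_study(cfg.simulate, sim_dir)
            genes = read_gff3(os.path.join(sim_dir, "genes.gff3"))
            for name in sorted(os.listdir(sim_dir)):
                outputs.append(os.path.join(sim_dir, name))
        else:
            sheet = read_sample_sheet(cfg.sample_sheet)
            genes = read_gff3(cfg.annotation)

        # --- classify + aggregate per sample ------------------------------
        summary_rows = []
        sample_gene_tables: dict[str, pd.DataFrame] = {}
        condition_of: dict[str, str] = {}
        chrom_counts = []
        for row in sheet.rows():
            sid = row["sample_id"]
            report = read_cytosine_report(row["report_path"])
            classified = classify_sites(report, genes, fcfg)
            emit(classified, f"{sid}.classified.tsv", 2)
            stats_ = summarize(classified, fcfg)
            sframe = stats_.to_frame()
            sframe.insert(0, "sample_id", sid)
            summary_rows.append(sframe)
            gt = aggregate_genes(classified, sid, fcfg)
            emit(gt, f"{sid}.genes.tsv", 4)
            sample_gene_tables[sid] = gt
            condition_of[sid] = row["condition"]
            chrom_counts.append(chrom_context_counts(classified, sid, fcfg))
        emit(pd.concat(summary_rows, ignore_index=True), "summary_stats.tsv", 2)
        chrom_table = pd.concat(chrom_counts, ignore_index=True)
        chrom_table["condition"] = chrom_table["sample_id"].map(condition_of)
        emit(chrom_table, "chrom_context_counts.tsv", 0)

        # one gene table per condition (replicates pooled by summing reads)
        condition_tables = _pool_by_condition(sample_gene_tables, condition_of, fcfg)

        # --- contrasts -----------------------------------------------------
        for i, cspec in enumerate(cfg.contrasts):
            try:
                results = contrast_family(
                    condition_tables,
                    cspec.reference_condition,
                    alpha=cspec.alpha,
                    dmg_delta_threshold=cspec.dmg_delta_threshold,
                    zero_method=cspec.zero_method,
                )
            except MethkitError as exc:
                logger.warning("contrast set %d failed: %s", i, exc)
                continue
            summary = pd.DataFrame([r.summary_row() for r in results])
            emit(summary, f"contrasts_{cspec.reference_condition}.summary.tsv", 4)
            for r in results:
                emit(
                    r.deltas,
                    f"deltas_{r.spec.test_condition}_vs_{r.spec.reference_condition}.tsv",
                    4,
                )

        # --- patterns ------------------------------------------------------
        matrix = build_matrix(condition_tables)
        if not matrix.empty and matrix.shape[1] >= 2:
            top = top_k_variable(matrix, cfg.patterns.top_k)
            try:
                pres = pca(top, scale=cfg.patterns.scale)
                scores = pres.scores.reset_index(names="sample_id")
                emit(scores, "pca_scores.tsv", 4)
                emit(
                    pd.DataFrame(
                        {
                            "component": scores.columns[1:],
                            "variance_explained": pres.explained_variance_ratio,
                        }
                    ),
                    "pca_variance.tsv",
                    6,
                )
            except MethkitError as exc:
                logger.warning("PCA skipped: %s", exc)
            clus = cluster_common_hyper(
                condition_tables, hyper_min_pct=cfg.patterns.hyper_min_pct
            )
            if clus is not None:
                path = os.path.join(cfg.output_dir, "dendrogram.nwk")
                with open(path, "w") as fh:
                    fh.write(clus.newick + "\n")
                outputs.append(path)
            meth_sets = {
                cond: set(t.loc[t["is_methylated_gene"].astype(bool), "gene_id"])
                for cond, t in condition_tables.items()
            }
            if len(meth_sets) >= 2:
                rep = overlap_counts(meth_sets)
                reports = rep if isinstance(rep, list) else [rep]
                frames = []
                for r in reports:
                    f = r.to_frame()
                    f.insert(0, "sets", "+".join(r.labels))
                    frames.append(f)
                emit(pd.concat(frames, ignore_index=True), "overlaps.tsv", 0)

        counts = pd.DataFrame(
            {
                "condition": list(condition_tables),
                "n_methylated_genes": [
                    count_methylated_genes(t) for t in condition_tables.values()
                ],
            }
        )
        emit(counts, "methylated_gene_counts.tsv", 0)
    finally:
        logging.getLogger("methkit").removeHandler(counter)

    manifest = RunManifest(
        version=__version__,
        config=_config_echo(cfg),
        checksums={os.path.relpath(p, cfg.output_dir): _sha256(p) for p in sorted(outputs)},
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        n_warnings=counter.count,
    )
    manifest.write(os.path.join(cfg.output_dir, "manifest.json"))
    return manifest


def _pool_by_condition(
    sample_tables: dict[str, pd.DataFrame],
    condition_of: dict[str, str],
    fcfg: FilterConfig,
) -> dict[str, pd.DataFrame]:
    """Pool replicate gene tables within a condition by summing read counts."""
    by_cond: dict[str, list[pd.DataFrame]] = {}
    for sid, table in sample_tables.items():
        by_cond.setdefault(condition_of[sid], []).append(table)
    pooled = {}
    for cond, tables in by_cond.items():
        if len(tables) == 1:
            pooled[cond] = tables[0].assign(sample_id=cond)
            continue
        cat = pd.concat(tables, ignore_index=True)
        g = cat.groupby("gene_id", sort=True).agg(
            n_exonic_sites=("n_exonic_sites", "sum"),
            meth_reads_sum=("meth_reads_sum", "sum"),
            total_reads_sum=("total_reads_sum", "sum"),
            n_cpg=("n_cpg", "sum"),
            n_chg=("n_chg", "sum"),
            n_chh=("n_chh", "sum"),
            n_hyper_positions=("n_hyper_positions", "sum"),
            is_methylated_gene=("is_methylated_gene", "any"),
        ).reset_index()
        g["level_pct"] = 100.0 * g["meth_reads_sum"] / g["total_reads_sum"]
        g["sample_id"] = cond
        pooled[cond] = g
    return pooled


def _config_echo(cfg: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    if cfg.simulate is not None:
        d["simulate"]["base_rates"] = dict(cfg.simulate.base_rates)
        if cfg.simulate.condition_effects is not None:
            d["simulate"]["condition_effects"] = dict(cfg.simulate.condition_effects)
    return d
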