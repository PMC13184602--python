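"""Synthetic bisulfite methylomes with known ground truth.

The generator emulates the statistical structure of a plant WGBS study after
alignment and methylation extraction, at desk scale:

* a random reference genome split into ``chr1..chrN`` chromosomes, with
  non-overlapping gene models (exons + introns) embedded in intergenic
  space;
* for every cytosine on both strands, a site-level methylation probability
  drawn from a beta distribution centred on a context-specific mean (high
  CpG, intermediate CHG, low CHH — the canonical plant gene-body pattern);
* read depth drawn from an overdispersed (negative-binomial) count
  distribution whose mean straddles the usual >=5 depth filter;
* methylated read counts binomial(depth, probability);
* treatment effects as additive shifts (percentage points / 100) applied to
  the site probabilities of *exonic* sites in a configurable fraction of
  genes, in the treated condition(s) only.

Baseline probabilities are a property of the genome: they are drawn once
from the config seed and shared across conditions, so the treated-minus-
control probability difference at an affected exonic site equals the imposed
effect exactly (up to clamping at 0/1). Everything is deterministic under a
fixed :class:`SimConfig`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CONTEXTS,
    GeneModel,
    MethkitError,
    SampleSheet,
    write_cytosine_report,
    write_fasta,
    write_gff3,
    write_table,
)
from .sites import annotate_region

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genome",
    "simulate_methylome",
    "simulate_study",
    "baseline_site_table",
    "affected_genes",
    "draw_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {65: 84, 67: 71, 71: 67, 84: 65, 78: 78}  # A<->T, C<->G, N->N on byte values


class ConfigError(MethkitError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the simulator; defaults give a small two-condition run.

    ``effect_size`` is in percentage points of methylation level; it is
    applied (as ``effect_size / 100`` on the probability scale) to exonic
    sites of an ``affected_fraction`` of genes in every non-reference
    condition of ``condition_effects``. ``condition_effects`` maps condition
    label -> shift in points; when ``None`` it defaults to
    ``{"control": 0, "treated": effect_size}``.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 2
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (1, 4)
    gene_length: tuple[int, int] = (200, 600)
    exon_fraction: float = 0.4
    base_rates: Mapping[str, float] = field(
        default_factory=lambda: {"CpG": 0.80, "CHG": 0.50, "CHH": 0.10}
    )
    rate_dispersion: float = 10.0
    depth_mean: float = 10.0
    depth_dispersion: float = 5.0
    effect_size: float = 0.0
    affected_fraction: float = 0.0
    condition_effects: Mapping[str, float] | None = None
    n_samples_per_condition: int = 1
    n_base_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exon_fraction", "affected_fraction", "n_base_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for ctx, r in self.base_rates.items():
            if ctx not in CONTEXTS:
                raise ConfigError(f"unknown context in base_rates: {ctx!r}")
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"base_rates[{ctx}] must lie in [0, 1], got {r}")
        if self.rate_dispersion <= 0 or self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("dispersion and depth parameters must be positive")
        if self.n_chromosomes < 1 or self.n_genes < 0 or self.n_samples_per_condition < 1:
            raise ConfigError("counts must be positive (n_genes may be zero)")
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ConfigError("exons_per_gene range must satisfy 1 <= lo <= hi")
        lo, hi = self.gene_length
        if not 3 <= lo <= hi:
            raise ConfigError("gene_length range must satisfy 3 <= lo <= hi")

    def resolved_condition_effects(self) -> dict[str, float]:
        if self.condition_effects is not None:
            return dict(self.condition_effects)
        return {"control": 0.0, "treated": self.effect_size}


@dataclass
class TruthTable:
    """Ground truth for one simulated methylome.

    ``sites`` has one row per emitted cytosine with its true context, region,
    gene and the probabilities used (``p_base`` before, ``p_applied`` after
    the condition shift); ``genes`` has the per-gene effect in points for
    this condition; ``condition`` is the sample's condition label.
    """

    condition: str
    sites: pd.DataFrame
    genes: pd.DataFrame

    def write(self, directory, prefix: str) -> None:
        os.makedirs(directory, exist_ok=True)
        write_table(self.sites, os.path.join(directory, f"{prefix}.truth_sites.tsv"), 6)
        write_table(self.genes, os.path.join(directory, f"{prefix}.truth_genes.tsv"), 6)


def _chrom_lengths(cfg: SimConfig) -> list[int]:
    base = cfg.genome_length // cfg.n_chromosomes
    lengths = [base] * cfg.n_chromosomes
    lengths[0] += cfg.genome_length - base * cfg.n_chromosomes
    return lengths


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Draw a reference sequence set and non-overlapping gene models.

    Raises :class:`ConfigError` when the genome cannot accommodate the
    requested genes with at least 1 bp of intergenic space between and
    around them.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    lengths = _chrom_lengths(cfg)
    sequences: dict[str, str] = {}
    for i, L in enumerate(lengths):
        seq = rng.choice(_BASES, size=L)
        if cfg.n_base_fraction > 0:
            ns = rng.random(L) < cfg.n_base_fraction
            seq[ns] = b"N"
        sequences[f"chr{i + 1}"] = seq.tobytes().decode()

    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return sequences, genes

    glo, ghi = cfg.gene_length
    gene_lengths = rng.integers(glo, ghi + 1, size=cfg.n_genes)
    chrom_of = np.arange(cfg.n_genes) % cfg.n_chromosomes

    for ci, L in enumerate(lengths):
        idx = np.flatnonzero(chrom_of == ci)
        if idx.size == 0:
            continue
        glens = gene_lengths[idx]
        free = L - int(glens.sum())
        m = idx.size
        if free < m + 1:
            raise ConfigError(
                f"chr{ci + 1} (length {L}) too small for {m} genes totalling {int(glens.sum())} bp"
            )
        gaps = 1 + rng.multinomial(free - (m + 1), np.full(m + 1, 1.0 / (m + 1)))
        cursor = 0
        for j, glen in enumerate(glens):
            cursor += int(gaps[j])
            start = cursor
            end = start + int(glen)
            cursor = end
            gid = f"gene{int(idx[j]) + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=f"chr{ci + 1}",
                    strand=strand,
                    start=start,
                    end=end,
                    exons=_draw_exons(rng, cfg, start, int(glen)),
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return sequences, genes


def _draw_exons(rng, cfg: SimConfig, start: int, glen: int) -> tuple[tuple[int, int], ...]:
    klo, khi = cfg.exons_per_gene
    k = int(rng.integers(klo, khi + 1))
    # shrink k until k exon bases + (k-1) intron bases fit the gene
    while k > 1 and glen - max(k, round(cfg.exon_fraction * glen)) < k - 1:
        k -= 1
    if k == 1:
        # single-exon gene: the exon spans the whole gene (zero introns)
        return ((start, start + glen),)
    exon_total = max(k, round(cfg.exon_fraction * glen))
    intron_total = glen - exon_total
    exon_sizes = 1 + rng.multinomial(exon_total - k, np.full(k, 1.0 / k))
    intron_sizes = 1 + rng.multinomial(intron_total - (k - 1), np.full(k - 1, 1.0 / (k - 1)))
    exons = []
    cursor = start
    for j in range(k):
        exons.append((cursor, cursor + int(exon_sizes[j])))
        cursor += int(exon_sizes[j])
        if j < k - 1:
            cursor += int(intron_sizes[j])
    # stretch the final exon to the gene end so the span is covered
    last_s, last_e = exons[-1]
    exons[-1] = (last_s, start + glen)
    return tuple(exons)


def _genome_cytosines(sequences: Mapping[str, str]) -> pd.DataFrame:
    """All cytosine sites on both strands with context and trinucleotide.

    Sites whose trinucleotide runs off the contig or contains an N are
    excluded (their context is undeterminable).
    """
    frames = []
    for chrom in sequences:
        arr = np.frombuffer(sequences[chrom].encode(), dtype="S1")
        L = arr.size
        if L < 3:
            continue
        for strand in "+-":
            if strand == "+":
                pos0 = np.flatnonzero(arr == b"C")
                pos0 = pos0[pos0 + 2 < L]
                b1, b2 = arr[pos0 + 1], arr[pos0 + 2]
                tri0 = arr[pos0]
            else:
                pos0 = np.flatnonzero(arr == b"G")
                pos0 = pos0[pos0 - 2 >= 0]
                # downstream on the minus strand = upstream on plus, complemented
                b1 = _complement(arr[pos0 - 1])
                b2 = _complement(arr[pos0 - 2])
                tri0 = _complement(arr[pos0])
            valid = (b1 != b"N") & (b2 != b"N")
            pos0, b1, b2, tri0 = pos0[valid], b1[valid], b2[valid], tri0[valid]
            context = np.where(b1 == b"G", "CpG", np.where(b2 == b"G", "CHG", "CHH"))
            tri = np.char.add(np.char.add(tri0, b1), b2).astype("U3")
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "context": context,
                        "tri": tri,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "tri"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def _complement(b: np.ndarray) -> np.ndarray:
    out = b.view(np.uint8).copy()
    for k, v in _COMP.items():
        out[b.view(np.uint8) == k] = v
    return out.view("S1")


def baseline_site_table(
    cfg: SimConfig, sequences: Mapping[str, str], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Annotated cytosines with their baseline methylation probabilities.

    Deterministic given the config (the probability draw uses its own seed
    stream, independent of condition and sample).
    """
    sites = _genome_cytosines(sequences)
    sites = annotate_region(sites, list(genes))
    rng = np.random.default_rng([cfg.seed, 23])
    p = np.empty(len(sites))
    ctx_arr = sites["context"].to_numpy()
    for ctx in CONTEXTS:
        mask = ctx_arr == ctx
        mean = float(cfg.base_rates.get(ctx, 0.0))
        if mean <= 0.0:
            p[mask] = 0.0
        elif mean >= 1.0:
            p[mask] = 1.0
        else:
            a = mean * cfg.rate_dispersion
            b = (1.0 - mean) * cfg.rate_dispersion
            p[mask] = rng.beta(a, b, size=int(mask.sum()))
    sites["p_base"] = p
    return sites


def draw_counts(
    cfg: SimConfig, p_applied: np.ndarray, condition_index: int, sample_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Depth and methylated-read draws for one sample.

    Depth is negative-binomial with mean ``depth_mean`` and dispersion
    ``depth_dispersion``; methylated reads are binomial(depth, p). The seed
    stream depends on (config seed, condition index, sample index) only, so
    replicate samples are independent yet reproducible.
    """
    rng = np.random.default_rng([cfg.seed, 53, condition_index, sample_index])
    r = cfg.depth_dispersion
    depth = rng.negative_binomial(r, r / (r + cfg.depth_mean), size=p_applied.size)
    meth = rng.binomial(depth, p_applied)
    return depth, meth


def affected_genes(cfg: SimConfig, genes: Sequence[GeneModel]) -> list[str]:
    """The deterministic subset of genes that receives the condition effect."""
    n_aff = int(round(cfg.affected_fraction * len(genes)))
    if n_aff == 0:
        return []
    rng = np.random.default_rng([cfg.seed, 37])
    ids = [g.gene_id for g in genes]
    return sorted(rng.choice(ids, size=n_aff, replace=False).tolist())


def simulate_methylome(
    cfg: SimConfig,
    sequences: Mapping[str, str],
    genes: Sequence[GeneModel],
    condition: str,
    sample_index: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Draw one per-cytosine report for ``condition`` plus its ground truth.

    The report has the 7 cytosine-report columns; context and trinucleotide
    are recomputed from the reference, so they agree with any downstream
    re-classification by construction. Unknown condition labels raise
    :class:`ConfigError`.
    """
    effects = cfg.resolved_condition_effects()
    if condition not in effects:
        raise ConfigError(
            f"unknown condition {condition!r}; configured: {sorted(effects)}"
        )
    truth_sites = baseline_site_table(cfg, sequences, genes)
    eff_points = float(effects[condition])
    aff = set(affected_genes(cfg, genes))
    shifted = (
        (truth_sites["region"] == "exonic").to_numpy()
        & truth_sites["gene_id"].isin(aff).to_numpy()
    )
    p_applied = truth_sites["p_base"].to_numpy().copy()
    if eff_points != 0.0:
        p_applied[shifted] = np.clip(p_applied[shifted] + eff_points / 100.0, 0.0, 1.0)
    truth_sites = truth_sites.assign(p_applied=p_applied)

    cond_idx = sorted(effects).index(condition)
    depth, meth = draw_counts(cfg, p_applied, cond_idx, sample_index)
    report = pd.DataFrame(
        {
            "chrom": truth_sites["chrom"].to_numpy(),
            "pos": truth_sites["pos"].to_numpy(),
            "strand": truth_sites["strand"].to_numpy(),
            "meth": meth,
            "unmeth": depth - meth,
            "context": truth_sites["context"].to_numpy(),
            "tri": truth_sites["tri"].to_numpy(),
        }
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "affected": [g.gene_id in aff for g in genes],
        }
    )
    gene_truth["effect_points"] = np.where(gene_truth["affected"], eff_points, 0.0)
    truth = TruthTable(condition=condition, sites=truth_sites, genes=gene_truth)
    return report, truth


def simulate_study(
    cfg: SimConfig, outdir: str | os.PathLike
) -> tuple[SampleSheet, dict[str, TruthTable]]:
    """Simulate a full study and write its files under ``outdir``.

    Writes ``reference.fa``, ``genes.gff3``, one cytosine report per sample
    (pooled: one sample per condition when ``n_samples_per_condition == 1``),
    per-sample truth tables, and ``samples.tsv``. Returns the sample sheet
    and the truth tables keyed by sample id.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    sequences, genes = simulate_genome(cfg)
    write_fasta(sequences, os.path.join(outdir, "reference.fa"))
    write_gff3(genes, os.path.join(outdir, "genes.gff3"))
    rows = []
    truths: dict[str, TruthTable] = {}
    for condition in sorted(cfg.resolved_condition_effects()):
        for rep in range(cfg.n_samples_per_condition):
            sample_id = (
                condition
                if cfg.n_samples_per_condition == 1
                else f"{condition}_rep{rep + 1}"
            )
            report, truth = simulate_methylome(cfg, sequences, genes, condition, rep)
            rel = f"{sample_id}.CX_report.txt"
            write_cytosine_report(report, os.path.join(outdir, rel))
            truth.write(outdir, sample_id)
            truths[sample_id] = truth
            rows.append((sample_id, "sim", condition, "S1", rel))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "condition", "stage", "report_path"]
    )
    write_table(frame, os.path.join(outdir, "samples.tsv"))
    frame = frame.assign(
        report_path=[os.path.join(outdir, p) for p in frame["report_path"]]
    )
    return SampleSheet(frame), truths
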