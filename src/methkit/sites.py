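"""Per-cytosine filtering and three-way annotation, plus genome-wide summaries.

Every cytosine site carries three independent labels:

* **sequence context** — CpG, CHG or CHH, read from the reference on the
  site's own strand (H is any base but G);
* **genomic region** — exonic, intronic or intergenic, from the gene models
  (exon beats intron when annotations overlap; gene strand is ignored);
* **methylation intensity** — hypomethylated (level <= 30%), intermediate
  (strictly between), or hypermethylated (level >= 70%).

Sites first pass a minimum-depth filter (default: total depth >= 5). A site
counts as *methylated* when it has at least one methylated read at a
depth-passing position; summaries report context / intensity / region
composition over methylated sites (and, alongside, over all depth-passing
sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

from .io import CONTEXTS, GeneModel, MethkitError

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "SummaryStats",
    "depth_filter",
    "classify_context",
    "annotate_region",
    "classify_intensity",
    "classify_intensities",
    "classify_sites",
    "summarize",
]

INTENSITIES = ("hypermethylated", "hypomethylated", "intermediate")
REGIONS = ("intergenic", "exonic", "intronic")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class FilterConfig:
    """Site filtering and intensity thresholds.

    min_depth : total reads required at a site (inclusive; default 5).
    require_both_strands : additionally require the strand-symmetric partner
        of a CpG/CHG site to pass ``min_depth``. CHH sites have no symmetric
        partner and are never subject to this extra check.
    hypo_max_pct / hyper_min_pct : intensity category boundaries in percent;
        level <= hypo_max_pct is hypomethylated, level >= hyper_min_pct is
        hypermethylated.
    min_meth_reads : methylated-read count that makes a site "methylated"
        for summary and gene-count purposes (default 1).
    min_meth_level_pct : optional extra level floor for calling a site
        methylated (default 0 = count alone decides).
    """

    min_depth: int = 5
    require_both_strands: bool = False
    hypo_max_pct: float = 30.0
    hyper_min_pct: float = 70.0
    min_meth_reads: int = 1
    min_meth_level_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise MethkitError("min_depth must be >= 1")
        if not (0 < self.hypo_max_pct < self.hyper_min_pct <= 100):
            raise MethkitError(
                "intensity thresholds must satisfy 0 < hypo_max < hyper_min <= 100"
            )


def depth_filter(sites: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep sites whose total depth is >= ``cfg.min_depth``.

    With ``require_both_strands`` set, a CpG site additionally needs its
    opposite-strand partner (the G of the same CpG dyad, one base away) to
    pass the depth cutoff, and a CHG site its partner two bases away.
    """
    cfg = cfg or FilterConfig()
    depth = sites["meth"] + sites["unmeth"]
    keep = depth >= cfg.min_depth
    out = sites.loc[keep]
    if not cfg.require_both_strands or out.empty:
        return out.copy()

    # partner offset on the opposite strand: CpG dyad +/-1, CHG triad +/-2
    sign = np.where(out["strand"].to_numpy() == "+", 1, -1)
    offset = np.select(
        [out["context"].to_numpy() == "CpG", out["context"].to_numpy() == "CHG"],
        [sign, 2 * sign],
        default=0,
    )
    partner_strand = np.where(out["strand"].to_numpy() == "+", "-", "+")
    passing = set(zip(out["chrom"], out["pos"], out["strand"]))
    symmetric = out["context"].isin(["CpG", "CHG"]).to_numpy()
    partner_ok = np.array(
        [
            (c, p + o, s) in passing
            for c, p, o, s in zip(out["chrom"], out["pos"], offset, partner_strand)
        ]
    )
    return out.loc[~symmetric | partner_ok].copy()


def classify_context(seq: str, pos: int, strand: str) -> str | None:
    """Sequence context of the cytosine at 1-based ``pos`` on ``strand``.

    Reads the next two bases downstream on the site's own strand:
    ``CG..`` -> CpG, ``C?G`` -> CHG, otherwise CHH. Returns ``None``
    (undeterminable) when the trinucleotide runs off the sequence end or
    contains an N; raises ``ValueError`` when the base at ``pos`` is not a
    cytosine on the requested strand.
    """
    i = pos - 1
    if not 0 <= i < len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"base at {pos}:+ is {seq[i]!r}, not C")
        tri = seq[i : i + 3]
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(f"base at {pos}:- is {seq[i]!r}, not C on the minus strand")
        tri = seq[max(0, i - 2) : i + 1][::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if len(tri) < 3 or "N" in tri:
        return None
    if tri[1] == "G":
        return "CpG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def annotate_region(
    sites: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Assign each site a region label and (for genic sites) a gene id.

    Precedence when annotations overlap: exonic > intronic > intergenic; a
    site falling in an exon of one gene and an intron of another is exonic
    and attributed to the exon's gene. Ties between genes are broken by
    (start, gene_id). Gene strand is ignored. Sites on chromosomes absent
    from the annotation are intergenic (logged once per chromosome).
    """
    out = sites.copy()
    out["region"] = "intergenic"
    out["gene_id"] = pd.NA
    if not genes or out.empty:
        return out

    known = {g.chrom for g in genes}
    unknown = sorted(set(out["chrom"]) - known)
    for chrom in unknown:
        logger.warning("chromosome %s absent from annotation; sites treated as intergenic", chrom)

    site_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": out["chrom"].to_numpy(),
                "Start": out["pos"].to_numpy() - 1,
                "End": out["pos"].to_numpy(),
                "site_idx": np.arange(len(out)),
            }
        )
    )

    def _assign(feature_frames: pd.DataFrame, label: str, mask_free: np.ndarray) -> None:
        ftr = pr.PyRanges(feature_frames)
        hit = site_pr.join(ftr).df
        if hit.empty:
            return
        hit = hit.sort_values(["Start_b", "g"]).drop_duplicates("site_idx", keep="first")
        idx = hit["site_idx"].to_numpy()
        take = mask_free[idx]
        idx = idx[take]
        out.iloc[idx, out.columns.get_loc("region")] = label
        out.iloc[idx, out.columns.get_loc("gene_id")] = hit["g"].to_numpy()[take]
        mask_free[idx] = False

    free = np.ones(len(out), dtype=bool)
    exon_df = pd.DataFrame(
        [
            (g.chrom, s, e, g.gene_id)
            for g in genes
            for (s, e) in g.exons
        ],
        columns=["Chromosome", "Start", "End", "g"],
    )
    span_df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id) for g in genes],
        columns=["Chromosome", "Start", "End", "g"],
    )
    _assign(exon_df, "exonic", free)
    _assign(span_df, "intronic", free)
    return out


def classify_intensity(level_pct: float, cfg: FilterConfig | None = None) -> str:
    """Intensity category of a single level (percent in [0, 100])."""
    cfg = cfg or FilterConfig()
    if not 0 <= level_pct <= 100:
        raise MethkitError(f"level {level_pct} outside [0, 100]")
    if level_pct <= cfg.hypo_max_pct:
        return "hypomethylated"
    if level_pct >= cfg.hyper_min_pct:
        return "hypermethylated"
    return "intermediate"


def classify_intensities(level_pct: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    cfg = cfg or FilterConfig()
    arr = np.asarray(level_pct, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise MethkitError("levels outside [0, 100]")
    return np.select(
        [arr <= cfg.hypo_max_pct, arr >= cfg.hyper_min_pct],
        ["hypomethylated", "hypermethylated"],
        default="intermediate",
    ).astype(object)


def classify_sites(
    report: pd.DataFrame,
    genes: list[GeneModel],
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Depth-filter a report and attach level, intensity and region labels.

    Returns a classified-site table with the report columns plus
    ``level_pct``, ``intensity``, ``region`` and ``gene_id``. Rows whose
    context is missing/undeterminable are dropped (logged).
    """
    cfg = cfg or FilterConfig()
    undet = ~report["context"].isin(CONTEXTS)
    if undet.any():
        logger.info("dropping %d sites with undeterminable context", int(undet.sum()))
        report = report.loc[~undet]
    kept = depth_filter(report, cfg)
    kept = kept.reset_index(drop=True)
    depth = (kept["meth"] + kept["unmeth"]).to_numpy()
    kept["level_pct"] = np.where(depth > 0, 100.0 * kept["meth"].to_numpy() / np.maximum(depth, 1), 0.0)
    kept["intensity"] = classify_intensities(kept["level_pct"].to_numpy(), cfg)
    kept = annotate_region(kept, genes)
    return kept


def _pct_triple(counts: dict[str, int], keys: tuple[str, ...]) -> dict[str, float]:
    total = sum(counts.get(k, 0) for k in keys)
    if total == 0:
        return {k: float("nan") for k in keys}
    return {k: 100.0 * counts.get(k, 0) / total for k in keys}


@dataclass
class SummaryStats:
    """Genome-wide composition of methylation calls (one sample).

    Counts are absolute; each ``pct_*`` mapping is the corresponding
    percentage triple with methylated sites as the denominator, so each
    triple sums to 100 whenever the methylated count is positive.
    ``pct_methylated_of_total`` uses all depth-passing sites as denominator.
    """

    n_total: int
    n_methylated: int
    n_plus: int
    n_minus: int
    context_counts: dict[str, int] = field(default_factory=dict)
    intensity_counts: dict[str, int] = field(default_factory=dict)
    region_counts: dict[str, int] = field(default_factory=dict)

    @property
    def pct_methylated_of_total(self) -> float:
        return 100.0 * self.n_methylated / self.n_total if self.n_total else float("nan")

    @property
    def pct_plus(self) -> float:
        return 100.0 * self.n_plus / self.n_methylated if self.n_methylated else float("nan")

    @property
    def pct_minus(self) -> float:
        return 100.0 * self.n_minus / self.n_methylated if self.n_methylated else float("nan")

    @property
    def pct_context(self) -> dict[str, float]:
        return _pct_triple(self.context_counts, CONTEXTS)

    @property
    def pct_intensity(self) -> dict[str, float]:
        return _pct_triple(self.intensity_counts, INTENSITIES)

    @property
    def pct_region(self) -> dict[str, float]:
        return _pct_triple(self.region_counts, REGIONS)

    @classmethod
    def from_counts(
        cls,
        n_total: int,
        n_methylated: int,
        n_plus: int,
        n_minus: int,
        context_counts: dict[str, int] | None = None,
        intensity_counts: dict[str, int] | None = None,
        region_counts: dict[str, int] | None = None,
    ) -> "SummaryStats":
        """Build a summary directly from precomputed counts (e.g. an external tally)."""
        if n_plus + n_minus != n_methylated:
            raise MethkitError("plus + minus strand counts must equal methylated count")
        return cls(
            n_total=n_total,
            n_methylated=n_methylated,
            n_plus=n_plus,
            n_minus=n_minus,
            context_counts=context_counts or {},
            intensity_counts=intensity_counts or {},
            region_counts=region_counts or {},
        )

    def to_frame(self) -> pd.DataFrame:
        """Summary-table layout: nine composition rows plus totals, counts alongside."""
        rows = []
        for k in CONTEXTS:
            rows.append((f"% {k}", self.pct_context[k], self.context_counts.get(k, 0)))
        for k in ("hypermethylated", "hypomethylated", "intermediate"):
            rows.append((f"% {k.capitalize()}", self.pct_intensity[k], self.intensity_counts.get(k, 0)))
        for k in REGIONS:
            rows.append((f"% {k.capitalize()}", self.pct_region[k], self.region_counts.get(k, 0)))
        rows.append(("% plus strand", self.pct_plus, self.n_plus))
        rows.append(("% minus strand", self.pct_minus, self.n_minus))
        rows.append(("% methylated of all sites", self.pct_methylated_of_total, self.n_methylated))
        rows.append(("total sites passing depth", float("nan"), self.n_total))
        return pd.DataFrame(rows, columns=["statistic", "percent", "count"])


def summarize(classified: pd.DataFrame, cfg: FilterConfig | None = None) -> SummaryStats:
    """Tally context / intensity / region / strand composition of methylated sites.

    ``classified`` is the output of :func:`classify_sites` (already
    depth-filtered). A site is methylated when it has at least
    ``cfg.min_meth_reads`` methylated reads and a level of at least
    ``cfg.min_meth_level_pct``.
    """
    cfg = cfg or FilterConfig()
    meth_mask = (classified["meth"] >= cfg.min_meth_reads) & (
        classified["level_pct"] >= cfg.min_meth_level_pct
    )
    m = classified.loc[meth_mask]
    return SummaryStats(
        n_total=int(len(classified)),
        n_methylated=int(len(m)),
        n_plus=int((m["strand"] == "+").sum()),
        n_minus=int((m["strand"] == "-").sum()),
        context_counts=m["context"].value_counts().to_dict(),
        intensity_counts=m["intensity"].value_counts().to_dict(),
        region_counts=m["region"].value_counts().to_dict(),
    )
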