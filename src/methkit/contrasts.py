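"""Contrast statistics for gene-level methylation between conditions.

For a test condition against a reference (mother plant for tissue-culture
stages, well-watered control for drought), the unit of analysis is the
per-gene delta

    delta_g = level_pct_test(g) - level_pct_ref(g)

over the gene universe: genes methylated in at least one of the two
conditions and covered (>= 1 exonic depth-passing site) in both. The
genome-wide effect size is the median of the deltas (the median shift), with
the across-loci standard deviation as the variability measure. Significance
comes from a paired Wilcoxon signed-rank test on the deltas, with
Benjamini-Hochberg FDR correction across the family of contrasts (e.g. all
stages against the mother plant). Differentially methylated genes (DMGs) are
genes with |delta| at or above a configurable threshold.

Chromosome-wise counts of hypermethylated exonic positions are compared
across condition x context groups by one-way ANOVA with chromosomes as
replicates, followed by Fisher's Least Significant Difference pairwise
comparisons summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MethkitError

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "per_gene_deltas",
    "median_shift",
    "wilcoxon_signed_rank",
    "wilcoxon_bh",
    "call_dmgs",
    "percent_change",
    "contrast_family",
    "anova_lsd",
    "AnovaLSDResult",
    "variability_across_stages",
]


class ContrastError(MethkitError):
    """A contrast that cannot be computed (e.g. empty gene universe)."""


@dataclass(frozen=True)
class ContrastSpec:
    """Definition of one test-vs-reference comparison."""

    test_condition: str
    reference_condition: str
    alpha: float = 0.05
    dmg_delta_threshold: float = 10.0
    zero_method: str = "wilcox"  # drop zero deltas before ranking (Pratt available)

    def __post_init__(self) -> None:
        if self.test_condition == self.reference_condition:
            raise MethkitError("test and reference conditions must differ")
        if not 0 < self.alpha < 1:
            raise MethkitError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.dmg_delta_threshold < 0:
            raise MethkitError("dmg_delta_threshold must be >= 0")


@dataclass
class ContrastResult:
    """Per-gene deltas plus the contrast-level summary statistics."""

    spec: ContrastSpec
    deltas: pd.DataFrame = field(repr=False)
    median_diff: float = float("nan")
    sd_loci: float = float("nan")
    wilcoxon_statistic: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    degenerate: bool = False
    n_genes: int = 0
    n_dmg: int = 0
    dmgs_per_100_points: float = float("nan")
    pct_change_methylated_genes: float = float("nan")

    def summary_row(self) -> dict:
        return {
            "test_condition": self.spec.test_condition,
            "reference_condition": self.spec.reference_condition,
            "n_genes": self.n_genes,
            "median_diff": self.median_diff,
            "sd_loci": self.sd_loci,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "degenerate": self.degenerate,
            "n_dmg": self.n_dmg,
            "dmgs_per_100_points": self.dmgs_per_100_points,
            "pct_change_methylated_genes": self.pct_change_methylated_genes,
        }


def per_gene_deltas(
    records_test: pd.DataFrame,
    records_ref: pd.DataFrame,
    spec: ContrastSpec,
) -> pd.DataFrame:
    """Delta table over the gene universe of one contrast.

    Universe: genes methylated in >= 1 of the two samples, restricted to
    genes covered in both. Genes covered in only one sample are dropped and
    the count logged. Raises :class:`ContrastError` on an empty universe.
    """
    cols = ["gene_id", "level_pct", "is_methylated_gene"]
    merged = records_test[cols].merge(
        records_ref[cols], on="gene_id", suffixes=("_test", "_ref"), how="outer",
        indicator=True,
    )
    one_sided = merged["_merge"] != "both"
    if one_sided.any():
        logger.info(
            "%s vs %s: dropped %d genes covered in only one condition",
            spec.test_condition, spec.reference_condition, int(one_sided.sum()),
        )
    both = merged.loc[~one_sided]
    universe = both.loc[
        both["is_methylated_gene_test"].astype(bool)
        | both["is_methylated_gene_ref"].astype(bool)
    ]
    if universe.empty:
        raise ContrastError(
            f"{spec.test_condition} vs {spec.reference_condition}: empty gene universe"
        )
    out = pd.DataFrame(
        {
            "gene_id": universe["gene_id"].to_numpy(),
            "level_test": universe["level_pct_test"].astype(float).to_numpy(),
            "level_ref": universe["level_pct_ref"].astype(float).to_numpy(),
        }
    )
    out["delta"] = out["level_test"] - out["level_ref"]
    return out.sort_values("gene_id").reset_index(drop=True)


def median_shift(deltas: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Sample median of the deltas and their across-loci SD (n-1 denominator).

    The median for even n is the mean of the two central order statistics;
    the SD is NaN for fewer than two deltas.
    """
    arr = np.asarray(deltas, dtype=float)
    if arr.size == 0:
        raise ContrastError("median shift undefined for zero deltas")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return float(np.median(arr)), sd


def wilcoxon_signed_rank(
    deltas: Sequence[float] | np.ndarray, zero_method: str = "wilcox"
) -> tuple[float, float, bool]:
    """Two-sided paired signed-rank test on the deltas.

    Returns (statistic, p, degenerate). Zero deltas are dropped before
    ranking by default (``zero_method='wilcox'``; ``'pratt'`` keeps them in
    the ranking). When every delta is zero the test is degenerate: p = 1
    with the flag set. The exact null distribution is used for n <= 25
    without ties; otherwise the normal approximation with continuity
    correction and midrank tie handling.
    """
    arr = np.asarray(deltas, dtype=float)
    nz = arr[arr != 0]
    if nz.size == 0:
        return float("nan"), 1.0, True
    has_ties = np.unique(np.abs(nz)).size < nz.size
    has_kept_zeros = zero_method == "pratt" and nz.size < arr.size
    method = "exact" if (nz.size <= 25 and not has_ties and not has_kept_zeros) else "approx"
    res = stats.wilcoxon(
        nz if zero_method == "wilcox" else arr,
        zero_method=zero_method,
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue), False


def wilcoxon_bh(
    delta_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Signed-rank p per contrast, BH-adjusted q across the family.

    ``delta_tables`` maps a contrast label (e.g. a tissue-culture stage) to
    its delta table. The BH family is exactly the set of contrasts passed in
    one call.
    """
    rows = []
    for label, table in delta_tables.items():
        statistic, p, degen = wilcoxon_signed_rank(table["delta"].to_numpy(), zero_method)
        rows.append((label, statistic, p, degen, len(table)))
    out = pd.DataFrame(
        rows, columns=["contrast", "statistic", "p_value", "degenerate", "n_genes"]
    )
    _, q, _, _ = multipletests(out["p_value"].to_numpy(), alpha=alpha, method="fdr_bh")
    out["q_value"] = q
    return out


def call_dmgs(deltas: pd.DataFrame, spec: ContrastSpec) -> tuple[pd.DataFrame, float]:
    """Genes with |delta| >= threshold, plus the per-100-points normalisation.

    The normalised count divides the DMG count by (observed |delta| range /
    100), giving a rate of DMGs per 100 points of observed methylation
    difference — one reading of a "per 100-point difference" comparison
    across varieties; NaN when the observed range is zero.
    """
    abs_delta = deltas["delta"].abs()
    # a gene with zero delta is never differentially methylated, even at threshold 0
    mask = (abs_delta >= spec.dmg_delta_threshold) & (abs_delta > 0)
    dmgs = deltas.loc[mask].copy()
    abs_d = deltas["delta"].abs()
    span = float(abs_d.max() - abs_d.min())
    per100 = float(len(dmgs) / (span / 100.0)) if span > 0 else float("nan")
    return dmgs, per100


def percent_change(count_ref: float, count_test: float) -> float:
    """Signed percent change from reference to test: 100*(test-ref)/ref."""
    if count_ref == 0:
        raise MethkitError("percent change undefined for a zero reference count")
    return 100.0 * (count_test - count_ref) / count_ref


def contrast_family(
    gene_tables: Mapping[str, pd.DataFrame],
    reference_condition: str,
    alpha: float = 0.05,
    dmg_delta_threshold: float = 10.0,
    zero_method: str = "wilcox",
) -> list[ContrastResult]:
    """All contrasts of the non-reference conditions against the reference.

    One BH family spans the whole set of contrasts. Methylated-gene percent
    change uses the counts from each sample's gene table.
    """
    if reference_condition not in gene_tables:
        raise ContrastError(f"reference condition {reference_condition!r} not present")
    from .genes import count_methylated_genes

    ref_records = gene_tables[reference_condition]
    n_ref = count_methylated_genes(ref_records)
    results: list[ContrastResult] = []
    delta_tables: dict[str, pd.DataFrame] = {}
    for label in sorted(gene_tables):
        if label == reference_condition:
            continue
        spec = ContrastSpec(
            test_condition=label,
            reference_condition=reference_condition,
            alpha=alpha,
            dmg_delta_threshold=dmg_delta_threshold,
            zero_method=zero_method,
        )
        deltas = per_gene_deltas(gene_tables[label], ref_records, spec)
        delta_tables[label] = deltas
        med, sd = median_shift(deltas["delta"].to_numpy())
        dmgs, per100 = call_dmgs(deltas, spec)
        res = ContrastResult(
            spec=spec,
            deltas=deltas,
            median_diff=med,
            sd_loci=sd,
            n_genes=len(deltas),
            n_dmg=len(dmgs),
            dmgs_per_100_points=per100,
        )
        if n_ref > 0:
            res.pct_change_methylated_genes = percent_change(
                n_ref, count_methylated_genes(gene_tables[label])
            )
        results.append(res)
    family = wilcoxon_bh(delta_tables, alpha=alpha, zero_method=zero_method)
    by_label = family.set_index("contrast")
    for res in results:
        row = by_label.loc[res.spec.test_condition]
        res.wilcoxon_statistic = float(row["statistic"])
        res.p_value = float(row["p_value"])
        res.q_value = float(row["q_value"])
        res.degenerate = bool(row["degenerate"])
    return results


@dataclass
class AnovaLSDResult:
    """One-way ANOVA over groups plus Fisher-LSD letter groupings."""

    f_statistic: float
    p_value: float
    mse: float
    df_resid: int
    groups: pd.DataFrame = field(repr=False)  # group, n, mean, letters
    pairwise: pd.DataFrame = field(repr=False)  # g1, g2, t, p, significant


def anova_lsd(
    counts: pd.DataFrame,
    value_col: str = "n_hyper_exonic_positions",
    group_cols: Sequence[str] = ("condition", "context"),
    alpha: float = 0.05,
) -> AnovaLSDResult:
    """One-way ANOVA across condition x context groups, then Fisher's LSD.

    Observations within a group are its chromosome-wise counts. Groups with
    fewer than two observations are excluded (warning). With zero residual
    variance the F statistic is infinite when group means differ (p = 0) and
    the letter display still proceeds; identical constant groups share one
    letter with p = 1.

    LSD comparisons use the pooled ANOVA error: for groups i, j the
    statistic is |mean_i - mean_j| / sqrt(MSE * (1/n_i + 1/n_j)) on the
    residual degrees of freedom. Letter assignment gives each maximal set of
    mutually non-different groups one letter, so groups sharing a letter
    never differ at level ``alpha``.
    """
    df = counts.copy()
    df["_group"] = df[list(group_cols)].astype(str).agg(":".join, axis=1)
    sizes = df.groupby("_group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding groups with <2 observations: %s", small)
        df = df[~df["_group"].isin(small)]
    groups = df.groupby("_group")[value_col]
    labels = list(groups.groups)
    if len(labels) < 2:
        raise MethkitError("ANOVA requires at least two groups with >=2 observations")
    values = [groups.get_group(g).to_numpy(dtype=float) for g in labels]
    ns = np.array([v.size for v in values])
    means = np.array([v.mean() for v in values])
    grand = np.concatenate(values).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = len(labels) - 1
    df_resid = int(ns.sum()) - len(labels)
    mse = ss_within / df_resid
    if mse > 0:
        f_stat = (ss_between / df_between) / mse
        p = float(stats.f.sf(f_stat, df_between, df_resid))
    elif ss_between > 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat, p = 0.0, 1.0

    pair_rows = []
    sig = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        diff = abs(means[i] - means[j])
        if mse > 0:
            t = diff / np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            pp = float(2 * stats.t.sf(t, df_resid))
        else:
            t = float("inf") if diff > 0 else 0.0
            pp = 0.0 if diff > 0 else 1.0
        s = (p < alpha) and (pp < alpha)  # protected LSD: only after significant ANOVA
        pair_rows.append((labels[i], labels[j], t, pp, s))
        sig[(i, j)] = sig[(j, i)] = s
    pairwise = pd.DataFrame(pair_rows, columns=["group1", "group2", "t", "p", "significant"])

    letters = _compact_letters(len(labels), sig, means)
    group_table = pd.DataFrame(
        {"group": labels, "n": ns, "mean": means, "letters": letters}
    ).sort_values("mean", ascending=False, kind="stable").reset_index(drop=True)
    return AnovaLSDResult(
        f_statistic=f_stat,
        p_value=p,
        mse=mse,
        df_resid=df_resid,
        groups=group_table,
        pairwise=pairwise,
    )


def _compact_letters(n: int, sig: dict, means: np.ndarray) -> list[str]:
    """Compact letter display: one letter per maximal clique of the
    non-significance graph, so sharing a letter implies not-different and
    not-different pairs always share at least one letter."""
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and not sig.get((i, j), False):
                adj[i].add(j)
    cliques: list[frozenset] = []
    if n <= 16:
        for size in range(n, 0, -1):
            for comb in itertools.combinations(range(n), size):
                s = set(comb)
                if all(s - {i} <= adj[i] for i in s):
                    if not any(s <= c for c in cliques):
                        cliques.append(frozenset(s))
    else:  # greedy fallback for very many groups
        remaining = set(range(n))
        order = sorted(remaining, key=lambda i: -means[i])
        for i in order:
            c = {i}
            for j in order:
                if j != i and all(j in adj[k] for k in c):
                    c.add(j)
            if not any(c <= set(cl) for cl in cliques):
                cliques.append(frozenset(c))
    # order letters by the highest group mean inside each clique
    cliques.sort(key=lambda c: -max(means[i] for i in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(n)]
    for letter, c in zip(alphabet, cliques):
        for i in c:
            letters[i] += letter
    return ["".join(sorted(l)) for l in letters]


def variability_across_stages(counts: Sequence[float]) -> float:
    """SD (n-1 denominator) of methylated-gene counts across stages; NaN for n < 2."""
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr, ddof=1))
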