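"""Depth filtering, context/region/intensity classification, and summaries."""

import numpy as np
import pandas as pd
import pytest

from methkit.io import GeneModel, MethkitError
from methkit.sites import (
    FilterConfig,
    SummaryStats,
    annotate_region,
    classify_context,
    classify_intensity,
    classify_sites,
    depth_filter,
    summarize,
)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"])


class TestDepthFilter:
    def test_boundary_inclusive_at_cutoff(self):
        df = _sites([("chr1", 1, "+", 2, 2, "CpG", "CGA"),   # depth 4: removed
                     ("chr1", 5, "+", 3, 2, "CpG", "CGA")])  # depth 5: retained
        out = depth_filter(df, FilterConfig(min_depth=5))
        assert out["pos"].tolist() == [5]

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        df = _sites(
            [
                ("chr1", int(p), "+", int(m), int(u), "CHH", "CAT")
                for p, m, u in zip(range(1, 1001), rng.integers(0, 6, 1000), rng.integers(0, 6, 1000))
            ]
        )
        survivors = {
            c: set(depth_filter(df, FilterConfig(min_depth=c))["pos"]) for c in (5, 6)
        }
        assert survivors[6] <= survivors[5]

    def test_both_strand_requirement_for_symmetric_contexts(self):
        # CpG dyad chr1:10(+)/11(-): only the + side passes depth
        df = _sites(
            [
                ("chr1", 10, "+", 5, 1, "CpG", "CGA"),
                ("chr1", 11, "-", 1, 1, "CpG", "CGT"),
                ("chr1", 50, "+", 4, 2, "CHH", "CAT"),  # CHH: never partner-checked
            ]
        )
        loose = depth_filter(df, FilterConfig(min_depth=5))
        assert loose["pos"].tolist() == [10, 50]
        strict = depth_filter(df, FilterConfig(min_depth=5, require_both_strands=True))
        assert strict["pos"].tolist() == [50]


class TestContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,want",
        [
            ("ACGTA", 2, "+", "CpG"),
            ("ACAGT", 2, "+", "CHG"),
            ("ACATT", 2, "+", "CHH"),
            ("ACGTA", 3, "-", "CpG"),  # G on plus is C on minus; downstream = complement of 2..1
            ("TAGAT", 3, "-", "CHH"),
            ("ACNTA", 2, "+", None),   # N inside the trinucleotide
            ("GAT", 1, "-", None),     # runs off the 5' end on minus
            ("TAC", 3, "+", None),     # runs off the 3' end on plus
        ],
    )
    def test_examples(self, seq, pos, strand, want):
        assert classify_context(seq, pos, strand) == want

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            classify_context("ACGTA", 1, "+")

    def test_minus_strand_agrees_with_reverse_complement_oracle(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        L = len(seq)
        for i, base in enumerate(seq):
            if base != "G":
                continue
            pos = i + 1
            # minus-strand context at pos == plus-strand context at the mirrored
            # position of the reverse complement
            want = classify_context(rc, L - i, "+")
            assert classify_context(seq, pos, "-") == want


class TestRegion:
    GENES = [GeneModel("g1", "chr1", "+", 99, 200, ((99, 150), (180, 200)))]

    @pytest.mark.parametrize(
        "pos,region,gene",
        [
            (120, "exonic", "g1"),
            (150, "exonic", "g1"),   # exon end, 1-based inclusive
            (160, "intronic", "g1"),
            (250, "intergenic", None),
        ],
    )
    def test_containment_examples(self, pos, region, gene):
        df = _sites([("chr1", pos, "+", 1, 1, "CpG", "CGA")])
        out = annotate_region(df, self.GENES)
        assert out.loc[0, "region"] == region
        assert (out.loc[0, "gene_id"] if region != "intergenic" else None) == gene

    def test_exon_precedence_over_other_genes_intron(self):
        genes = [
            GeneModel("host", "chr1", "+", 0, 1000, ((0, 10), (990, 1000))),
            GeneModel("nested", "chr1", "-", 100, 200, ((100, 200),)),
        ]
        df = _sites([("chr1", 150, "+", 1, 1, "CpG", "CGA")])
        out = annotate_region(df, genes)
        assert out.loc[0, "region"] == "exonic" and out.loc[0, "gene_id"] == "nested"

    def test_unknown_chromosome_is_intergenic(self):
        df = _sites([("chrX", 10, "+", 1, 1, "CpG", "CGA")])
        out = annotate_region(df, self.GENES)
        assert out.loc[0, "region"] == "intergenic"

    def test_agreement_with_per_base_brute_force(self, small_genome):
        sequences, genes = small_genome
        rng = np.random.default_rng(2)
        rows = []
        for chrom, seq in sequences.items():
            for pos in rng.integers(1, len(seq) + 1, size=5_000):
                rows.append((chrom, int(pos), "+", 1, 1, "CpG", "CGA"))
        df = _sites(rows)
        out = annotate_region(df, genes)
        # oracle: scan every gene of the list per position
        for row in out.itertuples(index=False):
            want = "intergenic"
            for g in genes:
                if g.chrom != row.chrom:
                    continue
                if any(s < row.pos <= e for s, e in g.exons):
                    want = "exonic"
                    break
                if g.start < row.pos <= g.end:
                    want = "intronic"
            assert row.region == want


class TestIntensity:
    @pytest.mark.parametrize(
        "level,want",
        [
            (30.0, "hypomethylated"),
            (70.0, "hypermethylated"),
            (50.0, "intermediate"),
            (30.0001, "intermediate"),
            (69.9999, "intermediate"),
            (0.0, "hypomethylated"),
            (100.0, "hypermethylated"),
            (60.0, "intermediate"),  # 3 meth / 5 reads
        ],
    )
    def test_threshold_boundaries(self, level, want):
        assert classify_intensity(level) == want

    def test_out_of_range_rejected(self):
        with pytest.raises(MethkitError):
            classify_intensity(101.0)


class TestSummaries:
    def test_context_percentages_over_methylated_sites(self):
        rows = (
            [("chr1", p, "+", 2, 3, "CpG", "CGA") for p in range(1, 6)]
            + [("chr1", p, "+", 2, 3, "CHG", "CAG") for p in range(10, 13)]
            + [("chr1", p, "+", 2, 3, "CHH", "CAT") for p in range(20, 22)]
        )
        classified = classify_sites(_sites(rows), [])
        s = summarize(classified)
        assert s.pct_context == {"CpG": 50.0, "CHG": 30.0, "CHH": 20.0}

    def test_zero_methylated_sites_reported_as_undefined(self):
        classified = classify_sites(_sites([("chr1", 1, "+", 0, 8, "CpG", "CGA")]), [])
        s = summarize(classified)
        assert s.n_methylated == 0 and np.isnan(s.pct_context["CpG"])

    def test_percentage_triples_sum_to_100(self, small_reports, small_genome):
        _, genes = small_genome
        report, _ = small_reports["control"]
        s = summarize(classify_sites(report, genes))
        for triple in (s.pct_context, s.pct_intensity, s.pct_region):
            assert sum(triple.values()) == pytest.approx(100.0, abs=0.01)
        assert s.n_plus + s.n_minus == s.n_methylated

    def test_raising_min_depth_never_increases_counts(self, small_reports, small_genome):
        _, genes = small_genome
        report, _ = small_reports["control"]
        s5 = summarize(classify_sites(report, genes, FilterConfig(min_depth=5)))
        s8 = summarize(classify_sites(report, genes, FilterConfig(min_depth=8)))
        assert s8.n_total <= s5.n_total and s8.n_methylated <= s5.n_methylated
        for attr in ("context_counts", "intensity_counts", "region_counts"):
            for k, v in getattr(s8, attr).items():
                assert v <= getattr(s5, attr).get(k, 0)

    def test_from_counts_strand_invariant_enforced(self):
        with pytest.raises(MethkitError):
            SummaryStats.from_counts(100, 50, 30, 10)
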