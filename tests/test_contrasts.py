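"""Median shifts, Wilcoxon + BH, DMG calling, percent change, ANOVA + LSD."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methkit.contrasts import (
    AnovaLSDResult,
    ContrastError,
    ContrastSpec,
    anova_lsd,
    call_dmgs,
    contrast_family,
    median_shift,
    per_gene_deltas,
    percent_change,
    variability_across_stages,
    wilcoxon_bh,
    wilcoxon_signed_rank,
)
from methkit.io import MethkitError


def _records(levels: dict[str, float], methylated: dict[str, bool] | None = None):
    methylated = methylated or {g: True for g in levels}
    return pd.DataFrame(
        {
            "gene_id": list(levels),
            "sample_id": "s",
            "n_exonic_sites": 5,
            "meth_reads_sum": 1,
            "total_reads_sum": 10,
            "level_pct": list(levels.values()),
            "n_cpg": 1,
            "n_chg": 1,
            "n_chh": 1,
            "n_hyper_positions": 0,
            "is_methylated_gene": [methylated[g] for g in levels],
        }
    )


SPEC = ContrastSpec("drought", "control")


class TestDeltas:
    def test_simple_difference(self):
        out = per_gene_deltas(_records({"g1": 35.0}), _records({"g1": 20.0}), SPEC)
        assert out.loc[0, "delta"] == pytest.approx(15.0)

    def test_identical_samples_give_zero_deltas(self):
        r = _records({"g1": 10.0, "g2": 55.0})
        out = per_gene_deltas(r, r, SPEC)
        assert (out["delta"] == 0).all()

    def test_universe_matches_set_arithmetic(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        test_genes = set(rng.choice(genes, 150, replace=False))
        ref_genes = set(rng.choice(genes, 150, replace=False))
        t = _records(
            {g: float(rng.uniform(0, 100)) for g in sorted(test_genes)},
            {g: bool(rng.random() < 0.7) for g in sorted(test_genes)},
        )
        r = _records(
            {g: float(rng.uniform(0, 100)) for g in sorted(ref_genes)},
            {g: bool(rng.random() < 0.7) for g in sorted(ref_genes)},
        )
        out = per_gene_deltas(t, r, SPEC)
        covered_both = test_genes & ref_genes
        meth_t = set(t.loc[t["is_methylated_gene"], "gene_id"])
        meth_r = set(r.loc[r["is_methylated_gene"], "gene_id"])
        want = covered_both & (meth_t | meth_r)
        assert set(out["gene_id"]) == want

    def test_empty_universe_raises(self):
        t = _records({"g1": 10.0}, {"g1": False})
        r = _records({"g2": 10.0}, {"g2": False})
        with pytest.raises(ContrastError, match="empty"):
            per_gene_deltas(t, r, SPEC)


class TestMedianShift:
    def test_constant_deltas(self):
        med, sd = median_shift([4.0, 4.0, 4.0])
        assert med == 4.0 and sd == 0.0

    def test_odd_n_median_is_central_order_statistic(self):
        med, _ = median_shift([-1, 0, 2, 3, 5])
        assert med == 2.0

    def test_even_n_median_averages_central_pair(self):
        med, _ = median_shift([1, 2, 3, 10])
        assert med == 2.5

    def test_sd_uses_n_minus_1(self):
        _, sd = median_shift([1.0, 3.0])
        assert sd == pytest.approx(math.sqrt(2))


def exact_signed_rank_p(deltas: np.ndarray) -> float:
    """Oracle: two-sided signed-rank p by enumerating all sign assignments."""
    d = deltas[deltas != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    observed = abs(w_plus - mean_w)
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= observed - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_six_positive_deltas_exact_p(self):
        deltas = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p, degen = wilcoxon_signed_rank(deltas)
        assert not degen
        assert p == pytest.approx(0.03125)
        assert p == pytest.approx(exact_signed_rank_p(deltas))

    def test_exact_p_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            deltas = rng.normal(0.4, 1.0, size=8)
            deltas = np.round(deltas, 3)
            if np.unique(np.abs(deltas[deltas != 0])).size < np.count_nonzero(deltas):
                continue  # oracle below assumes no ties
            _, p, _ = wilcoxon_signed_rank(deltas)
            assert p == pytest.approx(exact_signed_rank_p(deltas))

    def test_symmetric_deltas_give_p_one(self):
        _, p, degen = wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0]))
        assert not degen and p == pytest.approx(1.0)

    def test_all_zero_deltas_degenerate(self):
        _, p, degen = wilcoxon_signed_rank(np.zeros(10))
        assert degen and p == 1.0

    def test_bh_step_up_by_hand(self):
        tables = {
            "s1": pd.DataFrame({"delta": [1.0, 2.0, 3.0]}),
            "s2": pd.DataFrame({"delta": [1.0, 2.0, 3.0]}),
        }
        out = wilcoxon_bh(tables)
        # oracle on a hand-checkable p family
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert q.tolist() == pytest.approx([0.03, 0.03, 0.04])
        # q never below p, monotone in p
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()


class TestDMG:
    DELTAS = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "delta": [15.0, 5.0, -12.0],
                           "level_test": 0.0, "level_ref": 0.0})

    def test_threshold_selects_large_shifts(self):
        dmgs, _ = call_dmgs(self.DELTAS, ContrastSpec("d", "c", dmg_delta_threshold=10))
        assert set(dmgs["gene_id"]) == {"g1", "g3"}

    def test_threshold_zero_keeps_all_nonzero(self):
        df = pd.DataFrame({"gene_id": ["a", "b"], "delta": [0.0, 0.1],
                           "level_test": 0.0, "level_ref": 0.0})
        dmgs, _ = call_dmgs(df, ContrastSpec("d", "c", dmg_delta_threshold=0))
        assert set(dmgs["gene_id"]) == {"b"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(300)],
                           "delta": rng.normal(0, 15, 300),
                           "level_test": 0.0, "level_ref": 0.0})
        at10, _ = call_dmgs(df, ContrastSpec("d", "c", dmg_delta_threshold=10))
        at20, _ = call_dmgs(df, ContrastSpec("d", "c", dmg_delta_threshold=20))
        assert set(at20["gene_id"]) <= set(at10["gene_id"])


class TestPercentChange:
    def test_decrease_magnitude_rounds_to_seven(self):
        pc = percent_change(91_679, 85_199)
        assert pc == pytest.approx(-7.0681, abs=1e-4)
        assert round(abs(pc)) == 7

    def test_direct_arithmetic_on_printed_counts(self):
        assert percent_change(74_765, 88_596) == pytest.approx(18.50, abs=0.005)

    def test_no_change(self):
        assert percent_change(100, 100) == 0.0

    def test_zero_reference_flagged(self):
        with pytest.raises(MethkitError):
            percent_change(0, 10)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.integers(min_value=1, max_value=10**6),
        b=st.integers(min_value=1, max_value=10**6),
    )
    def test_antisymmetry_identity(self, a, b):
        # 100*(b-a)/a == -(100*(a-b)/b) * b/a
        lhs = percent_change(a, b)
        rhs = -percent_change(b, a) * b / a
        assert lhs == pytest.approx(rhs, rel=1e-9)


def _counts(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for label, values in groups.items():
        cond, ctx = label.split(":")
        for i, v in enumerate(values):
            rows.append((cond, ctx, f"chr{i + 1}", v))
    return pd.DataFrame(rows, columns=["condition", "context", "chrom", "n_hyper_exonic_positions"])


class TestAnovaLSD:
    def test_identical_constant_groups_share_one_letter(self):
        res = anova_lsd(_counts({"a:CpG": [5, 5, 5], "b:CpG": [5, 5, 5]}))
        assert res.f_statistic == 0.0 and res.p_value == 1.0
        assert set(res.groups["letters"]) == {"a"}

    def test_separated_constant_groups_get_distinct_letters(self):
        res = anova_lsd(_counts({"a:CpG": [10, 10, 10], "b:CpG": [100, 100, 100]}))
        assert res.p_value == 0.0 and math.isinf(res.f_statistic)
        letters = dict(zip(res.groups["group"], res.groups["letters"]))
        assert not set(letters["a:CpG"]) & set(letters["b:CpG"])

    def test_f_and_p_match_scipy_oneway(self):
        rng = np.random.default_rng(6)
        g = {
            "a:CpG": rng.normal(10, 2, 8).tolist(),
            "b:CpG": rng.normal(12, 2, 8).tolist(),
            "c:CpG": rng.normal(9, 2, 8).tolist(),
        }
        res = anova_lsd(_counts(g))
        f, p = stats.f_oneway(*g.values())
        assert res.f_statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_balanced_two_group_lsd_equals_pooled_t_test(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 3, 10)
        b = rng.normal(14, 3, 10)
        res = anova_lsd(_counts({"a:CpG": a.tolist(), "b:CpG": b.tolist()}))
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.pairwise.loc[0, "t"] == pytest.approx(abs(t))
        assert res.pairwise.loc[0, "p"] == pytest.approx(p)

    def test_groups_sharing_a_letter_never_differ(self):
        rng = np.random.default_rng(8)
        g = {f"c{i}:CpG": rng.normal(10 + 3 * i, 4, 6).tolist() for i in range(4)}
        res = anova_lsd(_counts(g))
        letters = dict(zip(res.groups["group"], res.groups["letters"]))
        pw = {
            frozenset((r.group1, r.group2)): r.significant
            for r in res.pairwise.itertuples()
        }
        for pair, significant in pw.items():
            g1, g2 = sorted(pair)
            if set(letters[g1]) & set(letters[g2]):
                assert not significant
            else:
                assert significant

    def test_undersized_group_excluded(self):
        df = _counts({"a:CpG": [1, 2, 3], "b:CpG": [4, 5, 6]})
        df = pd.concat(
            [df, pd.DataFrame([("c", "CpG", "chr1", 9)], columns=df.columns)],
            ignore_index=True,
        )
        res = anova_lsd(df)
        assert not res.groups["group"].str.startswith("c:").any()


class TestVariability:
    def test_constant_counts_have_zero_sd(self):
        assert variability_across_stages([10, 10, 10]) == 0.0

    def test_two_counts(self):
        assert variability_across_stages([1, 3]) == pytest.approx(math.sqrt(2))

    def test_translation_invariance(self):
        base = [100.0, 250.0, 180.0]
        shifted = [v + 5000 for v in base]
        assert variability_across_stages(base) == pytest.approx(
            variability_across_stages(shifted)
        )

    def test_single_value_undefined(self):
        assert math.isnan(variability_across_stages([42]))


class TestContrastFamily:
    def test_family_summary_and_q_values(self):
        rng = np.random.default_rng(9)
        genes = {f"g{i}": float(rng.uniform(10, 60)) for i in range(50)}
        ref = _records(genes)
        tables = {"control": ref}
        for label, shift in (("intermediate", 2.0), ("drought", 4.0)):
            tables[label] = _records({g: v + shift for g, v in genes.items()})
        results = contrast_family(tables, "control")
        by = {r.spec.test_condition: r for r in results}
        assert by["drought"].median_diff == pytest.approx(4.0)
        assert by["intermediate"].median_diff == pytest.approx(2.0)
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)
        assert by["drought"].pct_change_methylated_genes == pytest.approx(0.0)
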