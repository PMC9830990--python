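import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoexpr.datamodel import GeneSetMap, HomologyHitTable
from evoexpr.de import DEResult, call_de
from evoexpr.sexbias import (EnrichmentResult, MedianTestResult, OverlapTable,
                             best_hit_selection, candidate_enrichment,
                             classify_sex_bias, median_difference_test,
                             overlap_table, pearson_chi2, proportion_test,
                             sexbias_correlation, sexbias_de_enrichment,
                             term_enrichment)

from _oracles import hypergeom_upper_tail, two_proportion_z


def de_result(genes, log2fc, q, contrast="sex_in_E"):
    n = len(genes)
    table = pd.DataFrame({
        "gene": genes, "log2fc": log2fc, "mean_logcpm": np.zeros(n),
        "lr": np.zeros(n), "p": q, "q": q,
        "call": call_de(log2fc, q),
    })
    return DEResult(contrast=contrast, table=table, alpha=0.05,
                    fc_threshold=1.0)


class TestClassifySexBias:
    def test_fb_in_e_only(self):
        e = de_result(["g1", "g2"], [-2.0, 0.0], [0.01, 0.9])
        l = de_result(["g1", "g2"], [-0.2, 0.0], [0.5, 0.9], "sex_in_L")
        sb = classify_sex_bias(e, l)
        row = sb.table.set_index("gene").loc["g1"]
        assert row["class_E"] == "FB" and row["class_L"] == "UB"
        assert row["biased_either"]

    def test_unbiased_both(self):
        e = de_result(["g1"], [0.1], [0.8])
        l = de_result(["g1"], [0.1], [0.8], "sex_in_L")
        sb = classify_sex_bias(e, l)
        assert sb.table.loc[0, "class_E"] == "UB"
        assert not sb.table.loc[0, "biased_either"]

    def test_significant_but_small_fc_is_ub(self):
        e = de_result(["g1"], [0.5], [0.01])
        l = de_result(["g1"], [0.5], [0.01], "sex_in_L")
        sb = classify_sex_bias(e, l)
        assert sb.table.loc[0, "class_E"] == "UB"

    def test_gene_mismatch_rejected(self):
        e = de_result(["g1"], [0.0], [0.9])
        l = de_result(["g2"], [0.0], [0.9], "sex_in_L")
        with pytest.raises(ValueError, match="different genes"):
            classify_sex_bias(e, l)

    def test_agrees_with_call_de(self):
        """FB/MB iff the sex contrast calls down/up (male - female)."""
        rng = np.random.default_rng(0)
        n = 200
        fc = rng.normal(0, 2, n)
        q = rng.uniform(0, 0.2, n)
        genes = [f"g{i}" for i in range(n)]
        e = de_result(genes, fc, q)
        l = de_result(genes, np.zeros(n), np.ones(n), "sex_in_L")
        sb = classify_sex_bias(e, l)
        calls = call_de(fc, q)
        expect = np.where(calls == "down", "FB",
                          np.where(calls == "up", "MB", "UB"))
        assert (sb.table["class_E"].to_numpy() == expect).all()


class TestOverlapTable:
    def test_set_arithmetic(self):
        ov = overlap_table({"a", "b", "c"}, {"b", "c", "d"})
        assert (ov.female_only, ov.male_only, ov.both) == (1, 1, 2)
        assert ov.union == 4

    def test_disjoint(self):
        ov = overlap_table({"a", "b", "c"}, {"d", "e"})
        assert ov.both == 0 and ov.union == 5

    def test_additivity_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            uni = {f"g{i}" for i in range(50)}
            f = set(rng.choice(sorted(uni), rng.integers(0, 30), replace=False))
            m = set(rng.choice(sorted(uni), rng.integers(0, 30), replace=False))
            ov = overlap_table(f, m, universe=uni)
            assert ov.female_only + ov.male_only + ov.both == ov.union
            assert ov.union + ov.neither == len(uni)

    def test_restriction(self):
        ov = overlap_table({"a", "b"}, {"b", "c"}, universe={"a", "b", "c", "d"},
                           restrict_to={"a", "b"})
        assert ov.union == 2 and ov.male_only == 0


class TestProportionTest:
    def test_null_identity(self):
        chi2, df, p = proportion_test(10, 100, 10, 100)
        assert chi2 == 0.0 and p == 1.0 and df == 1

    def test_closed_form(self):
        chi2, _, p = proportion_test(30, 100, 10, 100)
        assert chi2 == pytest.approx(12.5)

    def test_extreme_table_valid(self):
        chi2, _, p = proportion_test(5, 5, 0, 5)
        assert np.isfinite(chi2) and 0 <= p <= 1

    def test_bad_input(self):
        with pytest.raises(ValueError):
            proportion_test(5, 0, 1, 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_z_squared(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(20, 200, 2)
        x1 = rng.integers(1, n1)
        x2 = rng.integers(1, n2)
        chi2, _, _ = proportion_test(int(x1), int(n1), int(x2), int(n2))
        z = two_proportion_z(int(x1), int(n1), int(x2), int(n2))
        assert chi2 == pytest.approx(z ** 2, rel=1e-9)


class TestSexbiasDeEnrichment:
    def _sb(self, classes):
        genes = [f"g{i}" for i in range(len(classes))]
        table = pd.DataFrame({
            "gene": genes, "class_E": classes, "class_L": ["UB"] * len(classes),
            "log2fc_E": 0.0, "log2fc_L": 0.0,
            "biased_either": [c != "UB" for c in classes]})
        from evoexpr.sexbias import SexBiasTable
        return SexBiasTable(table=table), set(genes)

    def test_extreme_enrichment(self):
        classes = ["FB"] * 10 + ["UB"] * 90
        sb, uni = self._sb(classes)
        de = {f"g{i}" for i in range(10)}  # exactly the FB genes
        chi2, p, odds = sexbias_de_enrichment(sb, de, uni, "FB")
        assert p < 1e-3 and odds == np.inf

    def test_empty_class_degenerate(self):
        sb, uni = self._sb(["UB"] * 20)
        with pytest.raises(ValueError, match="degenerate"):
            sexbias_de_enrichment(sb, {"g0"}, uni, "FB")

    def test_null_p_uniform(self):
        """Independent class/DE labels: p roughly uniform over 200 reps."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            classes = np.where(rng.uniform(size=300) < 0.3, "FB", "UB")
            sb, uni = self._sb(list(classes))
            de = set(np.array(sorted(uni))[rng.uniform(size=300) < 0.2])
            try:
                _, p, _ = sexbias_de_enrichment(sb, de, uni, "FB")
                pvals.append(p)
            except ValueError:
                pass
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestMedianDifferenceTest:
    def test_identical_vectors(self):
        x = np.arange(100.0)
        res = median_difference_test(x, x, n_boot=500, seed=0)
        assert abs(res.z) < 1e-9 and res.p == pytest.approx(1.0, abs=0.05)
        assert res.ci_low <= 0 <= res.ci_high

    def test_location_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        res = median_difference_test(x + 5, x, n_boot=2000, seed=0)
        assert res.z > 0 and res.p < 1e-6
        assert res.ci_low == pytest.approx(5, abs=0.5)
        assert res.ci_high == pytest.approx(5, abs=0.5)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=60)
        a = median_difference_test(x, y, n_boot=500, seed=9)
        b = median_difference_test(x, y, n_boot=500, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_z_sign_convention(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(size=100)
        res = median_difference_test(lo, lo + 3, n_boot=200, seed=0)
        assert res.z < 0

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = median_difference_test(np.ones(10), np.ones(12),
                                         n_boot=100, seed=0)
        assert res.p == 1.0


class TestSexbiasCorrelation:
    def _sb(self, fc_e, fc_l):
        n = len(fc_e)
        from evoexpr.sexbias import SexBiasTable
        table = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "class_E": ["FB"] * n, "class_L": ["FB"] * n,
            "log2fc_E": fc_e, "log2fc_L": fc_l,
            "biased_either": [True] * n})
        return SexBiasTable(table=table)

    def test_identity_correlation(self):
        fc = np.linspace(-3, 3, 20)
        res = sexbias_correlation(self._sb(fc, fc))
        assert res["r"] == pytest.approx(1.0)

    def test_df_is_n_minus_2(self):
        fc = np.linspace(-3, 3, 25)
        res = sexbias_correlation(self._sb(fc, fc + 0.1 * np.sin(fc)))
        assert res["df"] == 23

    def test_independent_biases_near_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = sexbias_correlation(self._sb(rng.normal(size=1000),
                                               rng.normal(size=1000)))
            hits += abs(res["r"]) < 0.1
        assert hits >= 19

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            sexbias_correlation(self._sb([1.0, 2.0], [1.0, 2.0]))


def hit_rows(rows):
    df = pd.DataFrame(rows, columns=["query_id", "subject_id", "e_value",
                                     "bit_score"])
    full = pd.DataFrame({
        "query_id": df["query_id"], "subject_id": df["subject_id"],
        "percent_identity": 90.0, "alignment_length": 100, "mismatches": 1,
        "gap_opens": 0, "q_start": 1, "q_end": 100, "s_start": 1, "s_end": 100,
        "e_value": df["e_value"], "bit_score": df["bit_score"],
    })[list(HomologyHitTable.COLUMNS)]
    return HomologyHitTable(rows=full)


class TestBestHitSelection:
    def test_min_evalue_wins(self):
        hits = hit_rows([("q1", "a", 1e-10, 100), ("q1", "b", 1e-5, 400)])
        best = best_hit_selection(hits)
        assert list(best["subject_id"]) == ["a"]

    def test_tie_broken_by_bitscore(self):
        hits = hit_rows([("q1", "a", 1e-10, 200), ("q1", "b", 1e-10, 554)])
        best = best_hit_selection(hits)
        assert list(best["subject_id"]) == ["b"]

    def test_full_tie_stable_first(self):
        hits = hit_rows([("q1", "a", 1e-10, 200), ("q1", "b", 1e-10, 200)])
        best = best_hit_selection(hits)
        assert list(best["subject_id"]) == ["a"]

    def test_empty(self):
        hits = hit_rows([("q1", "a", 1e-10, 100)])
        empty = HomologyHitTable(rows=hits.rows.iloc[0:0])
        assert len(best_hit_selection(empty)) == 0

    def test_multiple_queries(self):
        hits = hit_rows([("q1", "a", 1e-10, 100), ("q2", "b", 1e-3, 50),
                         ("q2", "c", 1e-8, 60)])
        best = best_hit_selection(hits)
        assert dict(zip(best["query_id"], best["subject_id"])) == {
            "q1": "a", "q2": "c"}


class TestCandidateEnrichment:
    def test_candidates_equal_de(self):
        uni = {f"g{i}" for i in range(1000)}
        de = {f"g{i}" for i in range(30)}
        chi2, p = candidate_enrichment(de, de, uni)
        assert p < 1e-10

    def test_depletion_valid(self):
        uni = {f"g{i}" for i in range(1000)}
        cands = {f"g{i}" for i in range(400)}
        de = {f"g{i}" for i in range(500, 900)}
        chi2, p = candidate_enrichment(cands, de, uni)
        assert np.isfinite(chi2) and 0 <= p <= 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            candidate_enrichment(set(), {"g1"}, {"g1", "g2"})

    def test_null_p_uniform(self):
        # sets large enough that the discrete chi-square p is near-continuous
        rng = np.random.default_rng(4)
        uni = np.array([f"g{i}" for i in range(2000)])
        pvals = []
        for _ in range(200):
            cands = set(rng.choice(uni, 400, replace=False))
            de = set(rng.choice(uni, 300, replace=False))
            _, p = candidate_enrichment(cands, de, set(uni))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestTermEnrichment:
    def test_closed_form(self):
        uni = {f"g{i}" for i in range(10)}
        sel = {f"g{i}" for i in range(5)}
        terms = GeneSetMap(sets={"T1": set(sel)})
        res = term_enrichment(sel, uni, terms)
        assert res.table.loc[0, "p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_selected_equals_universe(self):
        uni = {f"g{i}" for i in range(8)}
        terms = GeneSetMap(sets={"T1": {"g0", "g1"}, "T2": {"g5"}})
        res = term_enrichment(uni, uni, terms)
        assert (res.table["p"] == 1.0).all()

    def test_empty_intersection_skipped(self):
        uni = {"g0", "g1"}
        terms = GeneSetMap(sets={"T1": {"zzz"}, "T2": {"g0"}})
        res = term_enrichment({"g0"}, uni, terms)
        assert list(res.table["term"]) == ["T2"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_comb_oracle_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 16))
        uni = {f"g{i}" for i in range(N)}
        sel = set(rng.choice(sorted(uni), rng.integers(1, N), replace=False))
        term = set(rng.choice(sorted(uni), rng.integers(1, N), replace=False))
        res = term_enrichment(sel, uni, GeneSetMap(sets={"T": term}))
        k = len(term & sel)
        expect = hypergeom_upper_tail(k, N, len(term), len(sel))
        assert res.table.loc[0, "p"] == pytest.approx(expect, rel=1e-9)

    def test_expectation_overlap_moderate_p(self):
        rng = np.random.default_rng(5)
        uni = {f"g{i}" for i in range(1000)}
        term = set(np.array(sorted(uni))[:200])
        # selected at random: overlap near expectation, p not extreme
        pvals = []
        for _ in range(30):
            sel = set(rng.choice(sorted(uni), 100, replace=False))
            res = term_enrichment(sel, uni, GeneSetMap(sets={"T": term}))
            pvals.append(res.table.loc[0, "p"])
        assert 0.3 < np.median(pvals) < 0.9
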