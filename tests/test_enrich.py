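import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscout.enrich import (
    enrichment_score,
    permutation_significance,
    quartile_contrast,
    rank_genes,
    signal_to_noise,
    subtype_enrichment,
)
from oracles import bruteforce_enrichment_score, mannwhitney_exact_p


class TestQuartileContrast:
    def test_132_samples_give_33_per_group(self):
        expr = pd.Series(np.arange(132.0), index=[f"s{i:03d}" for i in range(132)])
        high, low = quartile_contrast(expr, 0.25)
        assert len(high) == len(low) == 33
        assert set(high).isdisjoint(low)

    def test_eight_samples_give_two_per_group(self):
        expr = pd.Series(np.arange(8.0), index=[f"s{i}" for i in range(8)])
        high, low = quartile_contrast(expr, 0.25)
        assert len(high) == len(low) == 2
        assert min(expr[high]) > max(expr[low])

    def test_ties_broken_by_sample_id(self):
        expr = pd.Series([1.0, 1.0, 0.0, 0.0], index=["b", "a", "d", "c"])
        high, low = quartile_contrast(expr, 0.25)
        assert high == ["a"] and low == ["c"]

    @pytest.mark.parametrize("q", [0.0, 0.5, 0.7, -0.1])
    def test_invalid_q_raises(self, q):
        with pytest.raises(ValueError):
            quartile_contrast(pd.Series(np.arange(20.0)), q)


class TestSignalToNoise:
    def test_identical_groups_give_zero(self):
        m = pd.DataFrame([[1, 2, 3, 1, 2, 3]], index=["g"], columns=list("abcdef"))
        assert signal_to_noise(m, ["a", "b", "c"], ["d", "e", "f"])["g"] == 0.0

    def test_direct_formula(self):
        # group A = (1,2,3): mean 2, sd 1; group B = (-1,0,1): mean 0, sd 1
        m = pd.DataFrame([[1, 2, 3, -1, 0, 1]], index=["g"], columns=list("abcdef"))
        assert signal_to_noise(m, ["a", "b", "c"], ["d", "e", "f"])["g"] == pytest.approx(1.0)

    def test_constant_gene_floored_to_zero(self):
        m = pd.DataFrame([[5.0] * 6], index=["g"], columns=list("abcdef"))
        assert signal_to_noise(m, ["a", "b", "c"], ["d", "e", "f"])["g"] == 0.0

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 8)), columns=list("abcdefgh"))
        a, b = list("abcd"), list("efgh")
        assert np.allclose(signal_to_noise(m, a, b), -signal_to_noise(m, b, a))

    def test_too_small_group_raises(self):
        m = pd.DataFrame([[1, 2, 3]], index=["g"], columns=list("abc"))
        with pytest.raises(ValueError):
            signal_to_noise(m, ["a"], ["b", "c"])


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    metric = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
    return rank_genes(metric)


class TestEnrichmentScore:
    def test_top_loaded_set_gives_plus_one_at_p0(self):
        ranked = _ranked(30)
        es, _, _ = enrichment_score(ranked, set(ranked.index[:5]), weight_p=0.0)
        assert es == pytest.approx(1.0)

    def test_bottom_loaded_set_gives_minus_one_at_p0(self):
        ranked = _ranked(30)
        es, _, _ = enrichment_score(ranked, set(ranked.index[-5:]), weight_p=0.0)
        assert es == pytest.approx(-1.0)

    def test_reversing_list_negates_es_at_p0(self):
        ranked = _ranked(40, seed=1)
        gene_set = set(np.random.default_rng(2).choice(ranked.index, 6, replace=False))
        es_fwd, _, _ = enrichment_score(ranked, gene_set, weight_p=0.0)
        es_rev, _, _ = enrichment_score(ranked.iloc[::-1], gene_set, weight_p=0.0)
        assert es_rev == pytest.approx(-es_fwd)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for i in range(50):
            ranked = _ranked(50, seed=100 + i)
            gene_set = set(rng.choice(ranked.index, 5, replace=False))
            hit = [g in gene_set for g in ranked.index]
            for p in (0.0, 1.0):
                es, _, _ = enrichment_score(ranked, gene_set, weight_p=p)
                assert es == pytest.approx(
                    bruteforce_enrichment_score(ranked.to_numpy(), hit, p), abs=1e-12
                )

    def test_leading_edge_subset_of_set(self):
        ranked = _ranked(50, seed=4)
        gene_set = set(ranked.index[::7])
        _, _, leading = enrichment_score(ranked, gene_set)
        assert set(leading) <= gene_set and leading

    def test_empty_or_full_set_raises(self):
        ranked = _ranked(10)
        with pytest.raises(ValueError):
            enrichment_score(ranked, set())
        with pytest.raises(ValueError):
            enrichment_score(ranked, set(ranked.index))


class TestPermutationSignificance:
    @staticmethod
    def _null_matrix(n_genes=60, n_samples=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{j:02d}" for j in range(n_samples)],
        )

    def test_fixed_seed_reproduces_everything(self):
        m = self._null_matrix()
        groups = (list(m.columns[:10]), list(m.columns[10:]))
        sets = {"A": list(m.index[:8]), "B": list(m.index[8:16])}
        r1 = permutation_significance(m, groups, sets, n_perm=50, seed=7)
        r2 = permutation_significance(m, groups, sets, n_perm=50, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_set_hits_p_floor(self):
        # shift one gene block strongly between groups; under gene-set
        # permutation no random set of that size reaches the observed |ES|,
        # so p sits at the plus-one-smoothed floor 1/(n_perm + 1)
        m = self._null_matrix(n_genes=100, seed=1)
        m.iloc[:10, :10] += 8.0
        groups = (list(m.columns[:10]), list(m.columns[10:]))
        sets = {"planted": list(m.index[:10])}
        res = permutation_significance(m, groups, sets, n_perm=100, mode="gene_set", seed=3)
        # no permuted set reaches the observed ES: p sits at the plus-one floor
        # of the same-sign null (1/(n_perm+1) when every permutation shares the sign)
        assert 1 / 101 <= res.loc["planted", "p_perm"] <= 0.02
        assert res.loc["planted", "es"] > 0.9

    def test_gene_set_mode_runs_and_is_calibrated_on_null(self):
        m = self._null_matrix(seed=2)
        groups = (list(m.columns[:10]), list(m.columns[10:]))
        sets = {f"S{i}": list(np.random.default_rng(i).choice(m.index, 8, replace=False))
                for i in range(40)}
        res = permutation_significance(m, groups, sets, n_perm=100, mode="gene_set", seed=5)
        assert stats.kstest(res["p_perm"], "uniform").pvalue > 0.01

    def test_small_group_or_nperm_raises(self):
        m = self._null_matrix()
        with pytest.raises(ValueError):
            permutation_significance(m, (list(m.columns[:2]), list(m.columns[2:])),
                                     {"A": list(m.index[:5])}, n_perm=20)
        with pytest.raises(ValueError):
            permutation_significance(m, (list(m.columns[:10]), list(m.columns[10:])),
                                     {"A": list(m.index[:5])}, n_perm=5)


class TestSubtypeEnrichment:
    def test_exact_worked_example(self):
        # class A = (1,2) vs rest = (3,4): U = 0, exact two-sided p = 1/3
        expr = pd.Series([1, 2, 3, 4], index=list("abcd"), dtype=float)
        labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        res = subtype_enrichment(expr, labels)
        assert res.loc["A", "U"] == 0.0
        assert res.loc["A", "p_value"] == pytest.approx(1 / 3)
        assert res.loc["A", "method"] == "exact"

    def test_identical_distributions_give_half_u(self):
        expr = pd.Series([5, 6, 5, 6], index=list("abcd"), dtype=float)
        labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        res = subtype_enrichment(expr, labels)
        assert res.loc["A", "U"] == 2.0  # n1*n2/2

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n1 in (2, 3, 4):
            for n2 in (2, 3, 4):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                idx = [f"s{i}" for i in range(n1 + n2)]
                expr = pd.Series(vals, index=idx)
                labels = pd.Series(["A"] * n1 + ["B"] * n2, index=idx)
                res = subtype_enrichment(expr, labels)
                p_oracle = mannwhitney_exact_p(list(vals[:n1]), list(vals[n1:]))
                assert res.loc["A", "p_value"] == pytest.approx(p_oracle, abs=1e-12)

    def test_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=16)
        p_exact = mannwhitney_exact_p(list(vals[:8]), list(vals[8:]))
        p_approx = stats.mannwhitneyu(vals[:8], vals[8:],
                                      alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.02

    def test_small_class_skipped_with_warning(self):
        expr = pd.Series(np.arange(7.0), index=[f"s{i}" for i in range(7)])
        labels = pd.Series(["A"] * 1 + ["B"] * 3 + ["C"] * 3, index=expr.index)
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = subtype_enrichment(expr, labels)
        assert "A" not in res.index and {"B", "C"} <= set(res.index)
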