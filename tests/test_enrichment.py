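"""Weighted enrichment scores, permutation nulls, hypergeometric and BH tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gwaspathnet.config import ConfigurationError
from gwaspathnet.enrichment import (
    compute_weights, gene_statistic, filter_pathways, enrichment_score,
    sum_statistic, permutation_null, empirical_p_and_nes,
    hypergeometric_test, bh_fdr, pathway_crosstalk, run_enrichment,
)
from gwaspathnet.study import PathwayCollection


# ------------------------------------------------------------------ oracles

def naive_es(wr_by_gene: dict, ranked_ids: list, members: set,
             p: float = 1.0) -> float:
    """Brute-force running sum, written independently of the library."""
    NR = sum(abs(wr_by_gene[g]) ** p for g in members)
    N, NH = len(ranked_ids), len(members)
    best, cum = -np.inf, 0.0
    for g in ranked_ids:
        if g in members:
            cum += abs(wr_by_gene[g]) ** p / NR
        else:
            cum -= 1.0 / (N - NH)
        best = max(best, cum)
    return best


def enumerate_hypergeom_tail(N, K, n, k):
    """P(X >= k) by enumerating all C(N, n) draws."""
    hits = total = 0
    pop = list(range(N))
    for draw in itertools.combinations(pop, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


# ------------------------------------------------------------------- weights

class TestComputeWeights:
    def test_formula_values(self):
        prior = pd.DataFrame({"gene_id": ["a", "b", "c"],
                              "CS": [2.0, 0.0, 4.0]})  # mean = 2
        w = compute_weights(prior, ["a", "b", "c", "d"])
        wmap = w.set_index("gene_id")["w"]
        assert wmap["a"] == pytest.approx(2.0)   # CS = CS_bar
        assert wmap["b"] == pytest.approx(1.0)   # CS = 0
        assert wmap["c"] == pytest.approx(3.0)   # CS = 2 CS_bar
        assert wmap["d"] == pytest.approx(1.0)   # unscored

    def test_all_zero_scores_rejected(self):
        prior = pd.DataFrame({"gene_id": ["a", "b"], "CS": [0.0, 0.0]})
        with pytest.raises(ValueError, match="equal_weight"):
            compute_weights(prior, ["a", "b"])

    def test_equal_weight_mode(self):
        prior = pd.DataFrame({"gene_id": ["a"], "CS": [5.0]})
        w = compute_weights(prior, ["a", "b"], equal_weight=True)
        assert (w["w"] == 1.0).all()

    def test_weights_at_least_one(self):
        rng = np.random.default_rng(0)
        prior = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)],
                              "CS": rng.gamma(2, 1, 50)})
        w = compute_weights(prior, prior["gene_id"])
        assert (w["w"] >= 1.0).all()


class TestGeneStatistic:
    def test_log_identities(self):
        scores = pd.DataFrame({"gene_id": ["a", "b"],
                               "p_adj": [1.0, np.exp(-1)]})
        t = gene_statistic(scores).set_index("gene_id")
        assert t.loc["a", "r"] == pytest.approx(0.0)
        assert t.loc["b", "r"] == pytest.approx(1.0)

    def test_zero_pvalue_floored_and_flagged(self):
        scores = pd.DataFrame({"gene_id": ["a"], "p_adj": [0.0]})
        t = gene_statistic(scores)
        assert bool(t["floored"][0])
        assert np.isfinite(t["r"][0]) and t["r"][0] > 600

    def test_ordering_is_total(self):
        scores = pd.DataFrame({"gene_id": ["b", "a", "c"],
                               "p_adj": [0.5, 0.5, 0.1]})
        t = gene_statistic(scores)
        assert list(t["gene_id"]) == ["c", "a", "b"]  # tie by gene_id


class TestFilterPathways:
    def _collection(self, sizes):
        universe = [f"u{i}" for i in range(500)]
        members = {f"p{j}": tuple(universe[:s]) for j, s in enumerate(sizes)}
        return PathwayCollection(members), universe

    def test_size_bounds_closed(self):
        coll, universe = self._collection([9, 10, 380, 381])
        kept = filter_pathways(coll, universe, 10, 380)
        assert set(kept.members) == {"p1", "p2"}

    def test_universe_intersection_counts(self):
        coll = PathwayCollection({"p": tuple(f"g{i}" for i in range(20))})
        universe = [f"g{i}" for i in range(12)]  # only 12 on the chip
        kept = filter_pathways(coll, universe, 10, 380)
        assert len(kept.universe_members["p"]) == 12
        assert len(kept.members["p"]) == 20


class TestEnrichmentScore:
    def test_worked_example(self, toy_ranked):
        # members at ranks 1 and 3: N_R = 6, prefix sums (2/3, 1/6, 1/2, 0)
        es = enrichment_score(toy_ranked, {"g1", "g3"})
        assert es == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_perfect_separation_reaches_one(self, toy_ranked):
        assert enrichment_score(toy_ranked, {"g1", "g2"}) == pytest.approx(1.0)

    def test_scale_invariance(self, toy_ranked):
        scaled = toy_ranked.copy()
        scaled["wr"] = scaled["wr"] * 10
        assert enrichment_score(scaled, {"g2", "g4"}) == pytest.approx(
            enrichment_score(toy_ranked, {"g2", "g4"}), rel=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            N = int(rng.integers(5, 51))
            ids = [f"g{i:02d}" for i in range(N)]
            wr = np.sort(rng.exponential(2.0, N))[::-1]
            ranked = pd.DataFrame({"gene_id": ids, "wr": wr})
            NH = int(rng.integers(1, N))
            members = set(rng.choice(ids, NH, replace=False))
            expected = naive_es(dict(zip(ids, wr)), ids, members)
            assert enrichment_score(ranked, members) == pytest.approx(
                expected, rel=1e-12)

    def test_es_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            N = int(rng.integers(4, 30))
            ids = [f"g{i}" for i in range(N)]
            ranked = pd.DataFrame({
                "gene_id": ids,
                "wr": np.sort(rng.gamma(1, 1, N))[::-1]})
            members = set(rng.choice(ids, int(rng.integers(1, N)),
                                     replace=False))
            es = enrichment_score(ranked, members)
            assert -1.0 < es <= 1.0 + 1e-12


class TestSumStatistic:
    def test_simple_sum(self):
        ranked = pd.DataFrame({"gene_id": ["a", "b", "c", "d"],
                               "wr": [2.0, 1.2, 0.8, 0.1]})
        assert sum_statistic(ranked, {"a", "b", "c"}) == pytest.approx(4.0)

    def test_all_zero_statistics(self):
        ranked = pd.DataFrame({"gene_id": ["a", "b"], "wr": [0.0, 0.0]})
        assert sum_statistic(ranked, {"a"}) == 0.0

    def test_empty_intersection_rejected(self):
        ranked = pd.DataFrame({"gene_id": ["a"], "wr": [1.0]})
        with pytest.raises(ValueError):
            sum_statistic(ranked, {"zz"})


class TestPermutationNull:
    def _setup(self, N=8, NH=3, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(N)]
        wr = np.sort(rng.exponential(1, N))[::-1]
        ranked = pd.DataFrame({"gene_id": ids, "wr": wr})
        coll = PathwayCollection({"p": tuple(ids[:NH])})
        coll.universe_members = {"p": tuple(ids[:NH])}
        return ranked, coll, wr

    def test_same_seed_identical_null(self):
        ranked, coll, _ = self._setup()
        a = permutation_null(coll, 50, seed=4, scheme="gene", ranked=ranked)
        b = permutation_null(coll, 50, seed=4, scheme="gene", ranked=ranked)
        assert np.array_equal(a["ES"], b["ES"])
        assert np.array_equal(a["SS"], b["SS"])

    def test_gene_scheme_ss_matches_without_replacement_draws(self):
        # every null SS must be a sum of NH distinct statistics, and the
        # sample mean must match the exact without-replacement expectation
        ranked, coll, wr = self._setup(N=6, NH=2, seed=3)
        null = permutation_null(coll, 4000, seed=1, scheme="gene",
                                ranked=ranked)
        achievable = {round(wr[i] + wr[j], 9)
                      for i, j in itertools.combinations(range(6), 2)}
        assert all(round(v, 9) in achievable for v in null["SS"][:, 0])
        expected_mean = 2 * wr.mean()
        assert null["SS"][:, 0].mean() == pytest.approx(expected_mean,
                                                        rel=0.05)

    def test_zero_permutations_rejected(self):
        ranked, coll, _ = self._setup()
        with pytest.raises(ConfigurationError):
            permutation_null(coll, 0, seed=0, scheme="gene", ranked=ranked)

    def test_phenotype_scheme_reproducible_and_shaped(self, small_bundle):
        from gwaspathnet.gene_scores import map_snps_to_genes
        b = small_bundle
        assignment = map_snps_to_genes(b.study.snps, b.gene_models)
        universe = list(assignment.gene_ids)
        coll = filter_pathways(b.pathways, universe, 5, 60)
        kw = dict(scheme="phenotype", study=b.study, assignment=assignment,
                  lam=1.0)
        a = permutation_null(coll, 10, seed=2, **kw)
        b_ = permutation_null(coll, 10, seed=2, **kw)
        assert np.array_equal(a["ES"], b_["ES"])
        assert np.array_equal(a["SS"], b_["SS"])
        assert a["ES"].shape == (10, len(coll))
        assert np.all(a["ES"] <= 1.0) and np.all(a["SS"] >= 0.0)


class TestEmpiricalPAndNes:
    def test_boundary_with_add_one_rule(self):
        p, _ = empirical_p_and_nes(10.0, np.linspace(0, 1, 100))
        assert p == pytest.approx(1.0 / 101.0)

    def test_centered_observation_has_zero_nes(self):
        nulls = np.array([0.1, 0.2, 0.3, 0.4])
        _, nes = empirical_p_and_nes(0.25, nulls)
        assert nes == pytest.approx(0.0)

    def test_counting_example(self):
        p, _ = empirical_p_and_nes(0.25, [0.1, 0.2, 0.3, 0.4])
        assert p == pytest.approx(3.0 / 5.0)

    def test_zero_variance_nes_undefined(self):
        p, nes = empirical_p_and_nes(0.5, [0.2, 0.2, 0.2])
        assert np.isnan(nes) and 0 < p <= 1


class TestHypergeometricTest:
    def test_enumeration_oracle(self):
        assert hypergeometric_test(10, 5, 4, 4) == pytest.approx(
            enumerate_hypergeom_tail(10, 5, 4, 4), rel=1e-12)
        assert hypergeometric_test(10, 5, 4, 4) == pytest.approx(5.0 / 210.0,
                                                                 rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeometric_test(100, 20, 10, 0) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(10, 5, 4, 5)

    def test_random_instances_vs_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            N = int(rng.integers(6, 12))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, min(N, 7)))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeometric_test(N, K, n, k) == pytest.approx(
                enumerate_hypergeom_tail(N, K, n, k), rel=1e-10)


class TestBhFdr:
    def test_stepup_rule_example(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.04, 0.05], q_star=0.05)
        assert reject.all()  # p(4) = 0.05 <= (4/4) 0.05

    def test_all_ones_rejected_none(self):
        reject, adj = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any() and (adj == 1.0).all()

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 40)
        _, adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_manual_stepup_agreement(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.74, 0.9])
        reject, _ = bh_fdr(p, 0.05)
        m = len(p)
        thresholds = (np.arange(1, m + 1) / m) * 0.05
        passing = np.nonzero(np.sort(p) <= thresholds)[0]
        k = passing.max() + 1 if passing.size else 0
        assert reject.sum() == k


class TestCrosstalk:
    def _collection(self, sets):
        coll = PathwayCollection({k: tuple(v) for k, v in sets.items()})
        coll.universe_members = dict(coll.members)
        return coll

    def _scores(self, genes):
        return pd.DataFrame({"gene_id": list(genes),
                             "p_adj": [0.01] * len(genes)})

    def test_disjoint_bin_none(self):
        coll = self._collection({"A": "abc", "B": "xyz"})
        t = pathway_crosstalk(coll, self._scores("abcxyz"))
        assert t["bin"][0] == "none" and t["n_overlap"][0] == 0

    def test_identical_bin_high(self):
        coll = self._collection({"A": "abc", "B": "abc"})
        t = pathway_crosstalk(coll, self._scores("abc"))
        assert t["proportion"][0] == pytest.approx(1.0)
        assert t["bin"][0] == ">70%"

    def test_partial_overlap_proportion(self):
        coll = self._collection({"A": ["a", "b", "c", "d", "e"],
                                 "B": ["d", "e", "f", "g", "h"]})
        t = pathway_crosstalk(coll, self._scores("abcdefgh"))
        assert t["n_overlap"][0] == 2
        assert t["proportion"][0] == pytest.approx(0.4)
        assert t["bin"][0] == "20-70%"


class TestWeightingIdentities:
    def test_equal_cs_reproduces_equal_weight_es(self, null_scores=None):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(40)]
        scores = pd.DataFrame({"gene_id": genes,
                               "p_adj": rng.uniform(0.001, 1, 40)})
        prior = pd.DataFrame({"gene_id": genes, "CS": [3.0] * 40})
        coll = PathwayCollection({"p1": tuple(genes[5:20]),
                                  "p2": tuple(genes[20:35])})
        coll = filter_pathways(coll, genes, 5, 40)
        rw = run_enrichment(scores, coll, prior, methods=("gsea", "ss"),
                            weighting="weighted", B=200, seed=2)
        re_ = run_enrichment(scores, coll, prior, methods=("gsea", "ss"),
                            weighting="equal", B=200, seed=2)
        gw = rw[rw["method"] == "wGSEA"].set_index("pathway_id")
        ge = re_[re_["method"] == "GSEA"].set_index("pathway_id")
        for pid in gw.index:
            assert gw.loc[pid, "ES"] == pytest.approx(ge.loc[pid, "ES"],
                                                      rel=1e-12)
            assert gw.loc[pid, "p_empirical"] == ge.loc[pid, "p_empirical"]
        # SS doubles under all-equal CS (w = 2) but its permutation p is
        # scale-equivariant, hence unchanged
        sw = rw[rw["method"] == "wSS"].set_index("pathway_id")
        se = re_[re_["method"] == "SS"].set_index("pathway_id")
        for pid in sw.index:
            assert sw.loc[pid, "SS"] == pytest.approx(2 * se.loc[pid, "SS"],
                                                      rel=1e-12)
            assert sw.loc[pid, "p_empirical"] == se.loc[pid, "p_empirical"]
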