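"""Hypergeometric enrichment, GSEA, prioritization, positional clusters."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dgepipe.pathways import (
    GeneSetCollection,
    GseaResult,
    TargetMap,
    core_gene_priority,
    gsea_es,
    gsea_rank_metric,
    hypergeom_enrich,
    mirna_priority,
    overlap_edges,
    positional_cluster_test,
)


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration of all n-subsets of the universe."""
    universe = range(N)
    members = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def _collection(sets, universe):
    return GeneSetCollection(
        {sid: frozenset(m) for sid, m in sets.items()}, universe=frozenset(universe)
    )


class TestHypergeomEnrich:
    def test_exact_enumeration_worked_example(self):
        # N=10, K=2, n=5, k=2 -> C(8,3)/C(10,5) = 2/9
        universe = [f"g{i}" for i in range(10)]
        coll = _collection({"S": universe[:2]}, universe)
        out = hypergeom_enrich(universe[:5], coll)
        want = hypergeom_tail_enumeration(10, 2, 5, 2)
        assert want == Fraction(2, 9)
        assert out.iloc[0]["p_hyper"] == pytest.approx(float(want), abs=1e-12)

    @pytest.mark.parametrize(
        "N,K,n", [(8, 3, 4), (10, 4, 5), (12, 5, 6), (9, 2, 3)]
    )
    def test_exact_enumeration_sweep(self, N, K, n):
        universe = [f"g{i}" for i in range(N)]
        coll = _collection({"S": universe[:K]}, universe)
        # query the first n genes: overlap k = min(K, n) known by construction
        out = hypergeom_enrich(universe[:n], coll)
        k = min(K, n)
        want = float(hypergeom_tail_enumeration(N, K, n, k))
        assert out.iloc[0]["k"] == k
        assert out.iloc[0]["p_hyper"] == pytest.approx(want, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        coll = _collection({"S": universe[5:7]}, universe)
        out = hypergeom_enrich(universe[:3], coll)
        assert out.iloc[0]["p_hyper"] == 1.0

    def test_empty_query_rejected(self):
        coll = _collection({"S": ["g0"]}, ["g0", "g1"])
        with pytest.raises(ValueError):
            hypergeom_enrich([], coll)

    def test_outside_universe_dropped_with_warning(self):
        coll = _collection({"S": ["g0"]}, ["g0", "g1"])
        with pytest.warns(UserWarning):
            out = hypergeom_enrich(["g0", "alien"], coll)
        assert out.iloc[0]["n"] == 1

    def test_frac_up_from_directions(self):
        universe = [f"g{i}" for i in range(6)]
        coll = _collection({"S": universe[:4]}, universe)
        directions = {"g0": "up", "g1": "down", "g2": "up", "g3": "up"}
        out = hypergeom_enrich(universe[:4], coll, directions)
        assert out.iloc[0]["frac_up"] == pytest.approx(0.75)

    def test_planted_enriched_set_ranks_first(self):
        rng = np.random.default_rng(55)
        universe = [f"g{i}" for i in range(300)]
        query = list(rng.choice(universe, 40, replace=False))
        planted = query[:20] + list(rng.choice(universe, 10, replace=False))
        sets = {"planted": set(planted)}
        for j in range(9):
            sets[f"bg{j}"] = set(rng.choice(universe, 30, replace=False))
        out = hypergeom_enrich(query, _collection(sets, universe))
        assert out.iloc[0]["set_id"] == "planted"


class TestGseaRankMetric:
    def test_mean_ratio_descending(self):
        rec = pd.DataFrame(
            {
                "feature_id": ["a", "a", "a", "b", "b", "b"],
                "log2_ratio": [2.0, 2.0, 2.0, 1.0, 1.0, 1.0],
            }
        )
        ranked = gsea_rank_metric(rec)
        assert list(ranked.index) == ["a", "b"]
        assert ranked["a"] == pytest.approx(2.0)

    def test_ties_broken_lexicographically(self):
        rec = pd.DataFrame(
            {"feature_id": ["c", "a", "b"], "log2_ratio": [1.0, 1.0, 1.0]}
        )
        assert list(gsea_rank_metric(rec).index) == ["a", "b", "c"]


def es_brute(scores, hit_flags, weight):
    """Exhaustive running-sum evaluation in exact arithmetic."""
    scores = [Fraction(s).limit_denominator(10**9) for s in scores]
    w = [abs(s) ** int(round(weight)) if weight else Fraction(1) for s in scores]
    total = sum(wi for wi, h in zip(w, hit_flags) if h)
    n_miss = sum(1 for h in hit_flags if not h)
    running, walk = Fraction(0), []
    for wi, h in zip(w, hit_flags):
        running += (wi / total) if h else -Fraction(1, n_miss)
        walk.append(running)
    best = max(walk, key=lambda v: (abs(v), v > 0))
    return float(best)


class TestGseaEs:
    def test_worked_example_unweighted(self):
        # N=5, hits at ranks 1 and 3, p=0: increments 1/2, decrements 1/3
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        res = gsea_es(ranked, {"a", "c"}, weight=0.0, n_perm=10)
        assert res.es == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert set(res.leading_edge) == {"a", "c"}

    def test_whole_list_set_degenerates_to_hit_walk(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        res = gsea_es(ranked, {"a", "b", "c"}, n_perm=10)
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == {"a", "b", "c"}

    def test_no_overlap_is_error(self):
        ranked = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            gsea_es(ranked, {"z"}, n_perm=10)

    def test_bottom_loaded_set_negative_es(self):
        ranked = pd.Series(np.linspace(3, -3, 10), index=[f"g{i}" for i in range(10)])
        res = gsea_es(ranked, {"g8", "g9"}, n_perm=10)
        assert res.es < 0
        assert set(res.leading_edge) == {"g8", "g9"}

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_exhaustive_oracle_sweep(self, weight):
        rng = np.random.default_rng(77)
        for _ in range(40):
            n = int(rng.integers(4, 21))
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            features = [f"g{i}" for i in range(n)]
            set_size = int(rng.integers(1, min(9, n)))
            members = set(rng.choice(features, set_size, replace=False))
            if set_size == n:
                continue
            ranked = pd.Series(scores, index=features)
            res = gsea_es(ranked, members, weight=weight, n_perm=5)
            brute = es_brute(scores, [f in members for f in features], weight)
            assert res.es == pytest.approx(brute, abs=1e-9)
            assert abs(res.es) <= 1.0 + 1e-12

    def test_permutation_p_reproducible_and_small_for_top_set(self):
        rng_scores = np.linspace(4, -4, 50)
        ranked = pd.Series(rng_scores, index=[f"g{i}" for i in range(50)])
        top = {f"g{i}" for i in range(5)}
        r1 = gsea_es(ranked, top, n_perm=500, rng=np.random.default_rng(9))
        r2 = gsea_es(ranked, top, n_perm=500, rng=np.random.default_rng(9))
        assert r1.p_perm == r2.p_perm
        assert r1.p_perm < 0.05 and r1.es > 0

    def test_leading_edge_subset_of_members(self):
        ranked = pd.Series(np.linspace(2, -2, 20), index=[f"g{i}" for i in range(20)])
        members = {"g1", "g5", "g15"}
        res = gsea_es(ranked, members, n_perm=10)
        assert set(res.leading_edge) <= members
        assert res.leading_edge  # nonzero ES -> non-empty leading edge


class TestPriorities:
    def test_core_gene_counting(self):
        results = {
            "P1": GseaResult("P1", 0.5, 0.01, ("A", "B")),
            "P2": GseaResult("P2", 0.4, 0.02, ("A",)),
            "P3": GseaResult("P3", -0.3, 0.03, ("B", "C")),
        }
        out = core_gene_priority(results, cancer_ids={"P1"})
        as_dict = out.set_index("feature_id")["n_pathways_total"].to_dict()
        assert as_dict == {"A": 2, "B": 2, "C": 1}
        cancer = out.set_index("feature_id")["n_pathways_cancer"].to_dict()
        assert cancer == {"A": 1, "B": 1, "C": 0}

    def test_gene_in_no_leading_edge_excluded(self):
        results = {"P1": GseaResult("P1", 0.5, 0.01, ("A",))}
        out = core_gene_priority(results)
        assert "Z" not in set(out["feature_id"])

    def test_mirna_set_semantics(self):
        results = {
            "P1": GseaResult("P1", 0.5, 0.01, ("A", "B")),
            "P2": GseaResult("P2", 0.4, 0.02, ("C",)),
        }
        tmap = TargetMap({"miR-1": frozenset({"A", "B"}), "miR-2": frozenset({"C"})})
        out = mirna_priority(tmap, results, cancer_ids={"P2"})
        d = out.set_index("feature_id")
        # two targets in one leading edge count the pathway once
        assert d.loc["miR-1", "n_pathways_total"] == 1
        assert d.loc["miR-2", "n_pathways_total"] == 1
        assert d.loc["miR-2", "n_pathways_cancer"] == 1

    def test_mirna_without_targets_warns_zero(self):
        results = {"P1": GseaResult("P1", 0.5, 0.01, ("A",))}
        tmap = TargetMap({"miR-x": frozenset()})
        with pytest.warns(UserWarning):
            out = mirna_priority(tmap, results)
        assert out.iloc[0]["n_pathways_total"] == 0


class TestTargetMap:
    def test_intersection_rule(self):
        exp = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["gE"]})
        pa = pd.DataFrame({"mirna_id": ["m1", "m1"], "gene_id": ["gP", "gA"]})
        pb = pd.DataFrame({"mirna_id": ["m1", "m1"], "gene_id": ["gP", "gB"]})
        tmap = TargetMap.from_tables(exp, pa, pb)
        assert tmap.targets["m1"] == frozenset({"gE", "gP"})
        assert tmap.evidence[("m1", "gE")] == "experimental"
        assert tmap.evidence[("m1", "gP")] == "predicted-intersection"


def _loci(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature_id"]
    )


class TestPositionalClusterTest:
    def _background(self, n=400, down=150, up=100):
        status = {}
        for i in range(n):
            status[f"m{i}"] = "down" if i < down else ("up" if i < down + up else "ns")
        return status

    def test_all_down_cluster_exact_tail(self):
        # 7 co-located miRNAs all down; 400 down of 726 detected
        status = {f"m{i}": ("down" if i < 400 else "ns") for i in range(726)}
        rows = [("chrX", 1000 + 2000 * j, 1100 + 2000 * j, "+", f"m{j}") for j in range(7)]
        loci = _loci(rows)
        out = positional_cluster_test(loci, status)
        down = out[out["direction"] == "down"].iloc[0]
        from scipy.stats import hypergeom

        want = float(hypergeom.sf(6, 726, 400, 7))
        assert down["k"] == 7
        assert down["p_hyper"] == pytest.approx(want, rel=1e-12)

    def test_two_member_run_is_not_a_cluster(self):
        status = {"m0": "down", "m1": "down"}
        loci = _loci([("chr1", 0, 100, "+", "m0"), ("chr1", 200, 300, "+", "m1")])
        assert len(positional_cluster_test(loci, status)) == 0

    def test_gap_threshold_splits_runs(self):
        status = {f"m{i}": "down" for i in range(6)}
        rows = [("chr1", i * 1000, i * 1000 + 100, "+", f"m{i}") for i in range(3)]
        rows += [("chr1", 100_000 + i * 1000, 100_000 + i * 1000 + 100, "+", f"m{i+3}") for i in range(3)]
        out = positional_cluster_test(_loci(rows), status)
        assert out["cluster_id"].nunique() == 2

    def test_invariant_to_row_order_and_translation(self):
        rng = np.random.default_rng(66)
        status = self._background()
        rows = [("chr5", 500 + 900 * j, 560 + 900 * j, "+", f"m{j}") for j in range(5)]
        rows += [("chr7", 10_000 + 800 * j, 10_060 + 800 * j, "-", f"m{j + 10}") for j in range(4)]
        loci = _loci(rows)
        base = positional_cluster_test(loci, status)
        shuffled = loci.sample(frac=1, random_state=3).reset_index(drop=True)
        translated = loci.assign(start=loci["start"] + 12_345, end=loci["end"] + 12_345)
        for variant in (shuffled, translated):
            out = positional_cluster_test(variant, status)
            pd.testing.assert_series_equal(
                base["p_hyper"].reset_index(drop=True),
                out["p_hyper"].reset_index(drop=True),
            )

    def test_loci_without_status_ignored(self):
        status = {f"m{i}": "down" for i in range(3)}
        rows = [("chr1", i * 1000, i * 1000 + 50, "+", f"m{i}") for i in range(3)]
        rows.append(("chr1", 3000, 3050, "+", "unknown"))
        out = positional_cluster_test(_loci(rows), status)
        assert out.iloc[0]["n_members"] == 3


class TestOverlapEdges:
    def test_jaccard_threshold(self):
        coll = _collection(
            {"A": ["g1", "g2", "g3"], "B": ["g2", "g3", "g4"], "C": ["g9"]},
            [f"g{i}" for i in range(1, 10)],
        )
        edges = overlap_edges(coll, min_jaccard=0.25)
        assert len(edges) == 1
        assert edges.iloc[0]["jaccard"] == pytest.approx(0.5)
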