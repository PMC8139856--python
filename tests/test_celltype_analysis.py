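"""Cell-type alignment scores, enriched gene pairs, transitivity,
hypergeometric enrichment, and one-to-one matching."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlasmap.celltype_analysis import (
    CellTypeGraph,
    bootstrap_transitivity_null,
    celltype_alignment_scores,
    differential_expression,
    enriched_gene_pairs,
    hypergeometric_enrichment,
    max_weight_one_to_one,
    transitivity,
)


class TestAlignmentScores:
    def test_toy_pair_scores_one(self):
        C1 = sp.csr_matrix(np.ones((2, 2)))  # 4 cross edges of weight 1
        C2 = sp.csr_matrix((2, 2))
        t = celltype_alignment_scores(C1, C2, ["a", "a"], ["b", "b"], k=1, z=0.0)
        assert len(t) == 1
        assert t["score"].iloc[0] == pytest.approx(1.0)

    def test_pairs_without_edges_dropped(self):
        C1 = sp.csr_matrix(np.array([[1.0, 0], [0, 0]]))
        t = celltype_alignment_scores(C1, sp.csr_matrix((2, 2)), ["a", "x"], ["b", "y"], k=1, z=0.0)
        assert set(zip(t["type_a"], t["type_b"])) == {("a", "b")}

    def test_threshold_z_filters(self):
        C1 = sp.csr_matrix(np.array([[0.1, 0], [0, 0]]))
        t = celltype_alignment_scores(C1, sp.csr_matrix((2, 2)), ["a", "x"], ["b", "y"], k=1, z=0.1)
        assert len(t) == 0  # 0.1 / ((1+1)*1) = 0.05 < z

    def test_unlabeled_cell_raises_with_indices(self):
        C1 = sp.csr_matrix((2, 2))
        with pytest.raises(ValueError, match="indices \\[1\\]"):
            celltype_alignment_scores(C1, sp.csr_matrix((2, 2)), ["a", None], ["b", "b"], k=1)

    def test_conservation_identity(self, small_result):
        """sum_ab s_ab (|c_a|+|c_b|) = (n1+n2) * S, to 1e-9."""
        from atlasmap.alignment import overall_alignment_score

        res = small_result
        k = res.cross.k
        t = celltype_alignment_scores(
            res.cross.C_1, res.cross.C_2, res.labels_1, res.labels_2, k=k, z=0.0
        )
        lhs = float((t["score"] * (t["n_cells_a"] + t["n_cells_b"])).sum())
        n1, n2 = res.cross.C_1.shape
        rhs = (n1 + n2) * overall_alignment_score(res.cross.C_1, res.cross.C_2, k=k)
        assert abs(lhs - rhs) < 1e-9


class TestDifferentialExpression:
    def test_matches_scipy_rank_sum_with_ties(self, rng):
        from scipy.stats import mannwhitneyu

        X = rng.poisson(2.0, size=(40, 6)).astype(float)  # ties guaranteed
        labels = np.array(["a"] * 15 + ["b"] * 25)
        de = differential_expression(X, labels)
        for g in range(6):
            p_mine = de[(de["label"] == "a") & (de["gene_index"] == g)]["p"].iloc[0]
            p_ref = mannwhitneyu(
                X[:15, g], X[15:, g], alternative="greater",
                method="asymptotic", use_continuity=False,
            ).pvalue
            assert p_mine == pytest.approx(p_ref, rel=1e-10)


class TestEnrichedGenePairs:
    def _setup(self):
        """5-gene toy: gene pair (a0, b0) is the top standardized outlier in
        both species for the mapped pair."""
        rng = np.random.default_rng(3)
        n = 10
        Z1 = rng.normal(0, 0.1, size=(2 * n, 5))
        Z2 = rng.normal(0, 0.1, size=(2 * n, 5))
        Z1[:n, 0] += 5.0  # type A marker
        Z2[:n, 0] += 5.0  # type B marker
        Z1[:n, 1] -= 5.0  # strongly negative in the mapped cells
        labels_1 = ["A"] * n + ["X"] * n
        labels_2 = ["B"] * n + ["Y"] * n
        C1 = sp.lil_matrix((2 * n, 2 * n))
        for i in range(n):
            C1[i, i] = 1.0
        C1 = C1.tocsr()
        C2 = C1.copy()
        linked = pd.DataFrame(
            {"gene_1": [f"a{i}" for i in range(5)], "gene_2": [f"b{i}" for i in range(5)]}
        )
        genes_1 = [f"a{i}" for i in range(5)]
        genes_2 = [f"b{i}" for i in range(5)]
        de = {(lab, g): 1e-5 for lab in ("A", "B", "X", "Y") for g in genes_1 + genes_2}
        w = {g: 1.0 for g in genes_1 + genes_2}
        return (C1, C2, labels_1, labels_2, Z1, Z2, genes_1, genes_2, linked, de, w)

    def test_double_outlier_ranks_first(self):
        C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, w = self._setup()
        t = enriched_gene_pairs(("A", "B"), C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, de, w, w)
        assert t["gene_1"].iloc[0] == "a0" and t["gene_2"].iloc[0] == "b0"

    def test_negative_standardized_truncated_to_zero(self):
        C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, w = self._setup()
        t = enriched_gene_pairs(("A", "B"), C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, de, w, w)
        # a1 has strongly negative standardized signature -> h_g = 0 -> absent
        assert "a1" not in set(t["gene_1"])

    def test_low_expressed_fraction_filtered(self):
        C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, w = self._setup()
        lognorm_1 = np.ones_like(Z1)
        lognorm_1[:, 0] = 0.0
        lognorm_1[0, 0] = 1.0  # a0 expressed in 10% > 5%: kept
        t = enriched_gene_pairs(
            ("A", "B"), C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, de, w, w,
            lognorm_1=lognorm_1, lognorm_2=np.ones_like(Z2),
        )
        assert bool(t.loc[t["gene_1"] == "a0", "passed"].iloc[0])
        lognorm_1[0, 0] = 0.0  # now 0% < 5%: filtered
        t = enriched_gene_pairs(
            ("A", "B"), C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, de, w, w,
            lognorm_1=lognorm_1, lognorm_2=np.ones_like(Z2),
        )
        assert not bool(t.loc[t["gene_1"] == "a0", "passed"].iloc[0])

    def test_unmapped_pair_warns_empty(self):
        C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, w = self._setup()
        with pytest.warns(UserWarning, match="unmapped"):
            t = enriched_gene_pairs(("A", "Y"), C1, C2, l1, l2, Z1, Z2, g1, g2, linked, de, de, w, w)
        assert len(t) == 0


def _graph(edges, nodes=None):
    e = pd.DataFrame(edges, columns=["node_a", "node_b", "score"])
    n = nodes or sorted(set(e["node_a"]) | set(e["node_b"]))
    return CellTypeGraph(nodes=list(n), edges=e)


def _oracle_transitivity(nodes, adj):
    """Exhaustive triad enumeration."""
    node_closed = {u: 0 for u in nodes}
    node_total = {u: 0 for u in nodes}
    edge_closed = {}
    edge_total = {}
    for u, v, w in itertools.combinations(nodes, 3):
        present = [(v in adj[u]), (w in adj[u]), (w in adj[v])]
        ne = sum(present)
        if ne < 2:
            continue
        closed = ne == 3
        for x in (u, v, w):
            node_total[x] += 1
            node_closed[x] += closed
        for a, b, here in (((u, v), (u, v), present[0]), ((u, w), (u, w), present[1]), ((v, w), (v, w), present[2])):
            if here:
                key = frozenset(a)
                edge_total[key] = edge_total.get(key, 0) + 1
                edge_closed[key] = edge_closed.get(key, 0) + closed
    node_t = {
        u: (node_closed[u] / node_total[u] if node_total[u] else 0.0) for u in nodes
    }
    edge_t = {
        k: edge_closed.get(k, 0) / edge_total[k] for k in edge_total
    }
    return node_t, edge_t


class TestTransitivity:
    def test_triangle_all_ones(self):
        g = transitivity(_graph([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]))
        assert np.allclose(g.edge_transitivity["edge_transitivity"], 1.0)
        assert np.allclose(g.node_transitivity, 1.0)

    def test_path_all_zero(self):
        g = transitivity(_graph([("a", "b", 1), ("b", "c", 1)]))
        assert np.allclose(g.edge_transitivity["edge_transitivity"], 0.0)
        assert g.node_transitivity["b"] == 0.0

    def test_random_graphs_match_exhaustive_enumeration(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 21))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.25:
                    edges.append((nodes[i], nodes[j], 1.0))
            if not edges:
                continue
            g = transitivity(_graph(edges, nodes))
            adj = {u: set() for u in nodes}
            for u, v, _ in edges:
                adj[u].add(v)
                adj[v].add(u)
            node_o, edge_o = _oracle_transitivity(nodes, adj)
            for u in nodes:
                assert g.node_transitivity[u] == pytest.approx(node_o[u], abs=1e-12)
            for _, r in g.edge_transitivity.iterrows():
                key = frozenset((r["node_a"], r["node_b"]))
                # an edge in no triad has transitivity 0 by convention
                assert r["edge_transitivity"] == pytest.approx(
                    edge_o.get(key, 0.0), abs=1e-12
                )


class TestBootstrapNull:
    def _graph(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]
        edges += [(f"x{i}", f"x{i+1}", 1) for i in range(6)]  # transitivity-0 chain
        return _graph(edges)

    def test_complete_graph_p_one(self):
        nodes = ["a", "b", "c", "d"]
        edges = [(u, v, 1.0) for u, v in itertools.combinations(nodes, 2)]
        p = bootstrap_transitivity_null(_graph(edges), ["a", "b"], reps=500, seed=0)
        assert p == 1.0

    def test_best_subset_small_p(self):
        p = bootstrap_transitivity_null(self._graph(), ["a", "b", "c"], reps=2000, seed=0)
        assert p < 0.05

    def test_fixed_seed_reproducible_to_last_digit(self):
        g = self._graph()
        p1 = bootstrap_transitivity_null(g, ["a", "x0", "x3"], reps=3000, seed=42)
        p2 = bootstrap_transitivity_null(g, ["a", "x0", "x3"], reps=3000, seed=42)
        assert p1 == p2

    def test_oversized_group_raises(self):
        with pytest.raises(ValueError, match="group size"):
            bootstrap_transitivity_null(self._graph(), [f"x{i}" for i in range(20)], reps=10)


class TestHypergeometric:
    def test_known_tail_fraction(self):
        """Population 10, 4 annotated, target 5, observed 3 -> p = 66/252."""
        background = [f"g{i}" for i in range(10)]
        target = ["g0", "g1", "g2", "g5", "g6"]
        terms = pd.DataFrame({"gene": ["g0", "g1", "g2", "g3"], "term": ["T"] * 4})
        out = hypergeometric_enrichment(target, background, terms)
        assert out["p"].iloc[0] == pytest.approx(66 / 252, abs=1e-12)
        assert out["count"].iloc[0] == 3

    def test_zero_observed_p_one(self):
        background = [f"g{i}" for i in range(8)]
        terms = pd.DataFrame({"gene": ["g6", "g7"], "term": ["T"] * 2})
        out = hypergeometric_enrichment(["g0", "g1"], background, terms)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_target_not_subset_raises(self):
        with pytest.raises(ValueError, match="missing from background"):
            hypergeometric_enrichment(["z"], ["g0"], pd.DataFrame({"gene": [], "term": []}))

    def test_matches_exact_enumeration(self, rng):
        """Direct combinatorial tail sum for populations <= 30."""
        for _ in range(20):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            background = [f"g{i}" for i in range(N)]
            annotated = list(rng.choice(background, size=K, replace=False))
            target = list(rng.choice(background, size=n, replace=False))
            x = len(set(annotated) & set(target))
            out = hypergeometric_enrichment(
                target, background, pd.DataFrame({"gene": annotated, "term": "T"})
            )
            oracle = sum(
                comb(K, i) * comb(N - K, n - i)
                for i in range(x, min(K, n) + 1)
                if n - i <= N - K
            ) / comb(N, n)
            assert out["p"].iloc[0] == pytest.approx(oracle, abs=1e-12)


class TestMaxWeightMatching:
    def test_known_optimum(self):
        out = max_weight_one_to_one([("a", "x", 5.0), ("a", "y", 3.0), ("b", "y", 4.0)])
        assert out == [("a", "x", 5.0), ("b", "y", 4.0)]

    def test_single_pair(self):
        assert max_weight_one_to_one([("a", "x", 2.0)]) == [("a", "x", 2.0)]

    def test_symmetric_conflict_deterministic(self):
        out1 = max_weight_one_to_one([("a", "x", 1.0), ("b", "x", 1.0)])
        out2 = max_weight_one_to_one([("b", "x", 1.0), ("a", "x", 1.0)])
        assert len(out1) == 1 and out1 == out2

    def test_matches_bruteforce_enumeration(self, rng):
        for trial in range(15):
            m1 = int(rng.integers(2, 6))
            m2 = int(rng.integers(2, 6))
            pairs = []
            for i in range(m1):
                for j in range(m2):
                    if rng.random() < 0.6:
                        pairs.append((f"a{i}", f"b{j}", float(rng.integers(1, 50))))
            if not pairs:
                continue
            got = max_weight_one_to_one(pairs)
            got_total = sum(w for _, _, w in got)
            # brute force: enumerate all matchings
            best = 0.0
            lhs = sorted({a for a, _, _ in pairs})
            wmap = {(a, b): w for a, b, w in pairs}
            rhs = sorted({b for _, b, _ in pairs})
            for r in range(min(len(lhs), len(rhs)), 0, -1):
                for lsub in itertools.combinations(lhs, r):
                    for rperm in itertools.permutations(rhs, r):
                        total = 0.0
                        ok = True
                        for a, b in zip(lsub, rperm):
                            if (a, b) not in wmap:
                                ok = False
                                break
                            total += wmap[(a, b)]
                        if ok:
                            best = max(best, total)
            assert got_total == pytest.approx(best)


class TestTransitivityEndpointReading:
    def test_endpoint_denominator_counts_all_incident_triads(self):
        # star + one triangle: edge (a, b) in triangle; c hangs off a
        g = _graph([("a", "b", 1), ("b", "d", 1), ("a", "d", 1), ("a", "c", 1)])
        edge_reading = transitivity(g, denominator="edge").edge_transitivity
        endpoint_reading = transitivity(g, denominator="endpoint").edge_transitivity
        ab_edge = edge_reading.set_index(["node_a", "node_b"]).loc[("a", "b")]
        ab_end = endpoint_reading.set_index(["node_a", "node_b"]).loc[("a", "b")]
        # edge reading: thirds adjacent to a or b = {c, d}; closed with d only
        assert ab_edge["edge_transitivity"] == pytest.approx(0.5)
        # endpoint reading: triads {a,b,d} closed, {a,b,c} open, {a,c,d} open
        assert ab_end["edge_transitivity"] == pytest.approx(1 / 3)

    def test_duplicate_pair_entries_use_best_weight(self):
        out = max_weight_one_to_one([("a", "x", 1.0), ("a", "x", 7.0)])
        assert out == [("a", "x", 7.0)]
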