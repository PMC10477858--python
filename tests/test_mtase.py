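"""MTase annotation, enrichment statistics, alignment and MCL clustering."""

import math

import networkx as nx
import numpy as np
import pytest

from phameth.mtase import (
    DomainHit,
    SimilarityEdge,
    align_proteins,
    alignment_significant,
    annotate_mtases,
    best_reference_hits,
    build_similarity_graph,
    categorize_clusters,
    classify_orphan,
    mcl_cluster,
    orphan_enrichment,
)


class TestAnnotation:
    def test_whitelist_and_cutoff(self):
        hits = [
            DomainHit("p1", "COG0350", 1e-6),
            DomainHit("p2", "pfam00001", 1e-50),
            DomainHit("p3", "TIGR00589", 1e-4),
            DomainHit("p4", "cd21179.smp", 1e-8),  # .smp suffix normalised
        ]
        assert annotate_mtases(hits) == {"p1", "p4"}

    def test_monotone_in_evalue_cutoff(self):
        hits = [DomainHit(f"p{i}", "COG0350", 10.0 ** (-i)) for i in range(1, 12)]
        prev = set()
        for cutoff in (1e-9, 1e-7, 1e-5, 1e-3):
            cur = annotate_mtases(hits, evalue_max=cutoff)
            assert prev <= cur
            prev = cur


class TestOrphanClassification:
    def test_best_hit_tie_breaking(self):
        edges = [
            SimilarityEdge("q", "b_subject", 80.0, 90.0, 1e-20),
            SimilarityEdge("q", "a_subject", 80.0, 90.0, 1e-20),
            SimilarityEdge("q", "c_subject", 99.0, 99.0, 1e-10),
        ]
        best = best_reference_hits(edges)
        assert best["q"].subject_id == "a_subject"  # lowest e, lexicographic tie

    def test_proportions_per_identity_bin(self):
        flags = {"non1": False, "non2": False, "orph": True}
        edges = [
            SimilarityEdge("m1", "non1", 95.0, 100.0, 1e-30),
            SimilarityEdge("m2", "orph", 60.0, 100.0, 1e-30),
            SimilarityEdge("m3", "non2", 40.0, 100.0, 1e-30),
        ]
        out = classify_orphan(["m1", "m2", "m3"], edges, flags)
        assert out[0.0]["n_with_hit"] == 3
        assert out[0.0]["proportion"] == pytest.approx(2 / 3)
        assert out[50.0]["n_with_hit"] == 2
        assert out[90.0] == {"n_with_hit": 1, "n_nonorphan": 1, "proportion": 1.0}

    def test_no_hits_no_bins(self):
        assert classify_orphan(["m1"], [], {}) == {}


class TestEnrichment:
    def test_tiny_exhaustive_case(self):
        out = orphan_enrichment(3, 3, 3, 6)
        # P(X >= 3) = C(3,3) C(3,0) / C(6,3) = 1/20
        assert out["p_hypergeometric"] == pytest.approx(0.05, abs=1e-12)

    def test_equal_proportions_chi2_zero(self):
        out = orphan_enrichment(10, 20, 50, 100)
        assert out["chi2_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_chi2"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small(self):
        # spot-check the upper-tail sum against direct combinatorics
        for (k, n, K, N) in [(2, 4, 5, 10), (1, 3, 6, 12), (4, 5, 8, 20)]:
            p = orphan_enrichment(k, n, K, N)["p_hypergeometric"]
            brute = sum(
                math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                for j in range(k, min(n, K) + 1)
            )
            assert p == pytest.approx(brute, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            orphan_enrichment(5, 3, 10, 20)


class TestAlignment:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        e = align_proteins(seq, seq)
        assert e.identity == pytest.approx(100.0)
        assert e.query_coverage == pytest.approx(100.0)
        assert e.simscore == pytest.approx(100.0)

    def test_substitution_pair_identity(self, rng):
        from phameth.simulate import AMINO_ACIDS, evolve_protein

        parent = "".join(rng.choice(list(AMINO_ACIDS), size=100))
        child = evolve_protein(parent, 0.90, rng)
        e = align_proteins(parent, child)
        assert e.identity == pytest.approx(90.0, abs=1.0)
        assert e.query_coverage == pytest.approx(100.0, abs=1.0)

    def test_unrelated_sequences_not_significant(self, rng):
        from phameth.simulate import AMINO_ACIDS

        a = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        b = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        assert not alignment_significant(a, b, n_shuffle=20, seed=0)
        assert alignment_significant(a, a, n_shuffle=20, seed=0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("", "MK")


class TestSimilarityGraph:
    def test_coverage_strictly_above_threshold(self):
        edges = [
            SimilarityEdge("a", "b", 90.0, 75.0, 1e-20),  # dropped: not > 75
            SimilarityEdge("a", "c", 90.0, 75.1, 1e-20),
        ]
        g = build_similarity_graph(edges)
        assert not g.has_edge("a", "b") and g.has_edge("a", "c")

    def test_symmetrisation_keeps_max(self):
        edges = [
            SimilarityEdge("a", "b", 90.0, 80.0, 1e-20),   # simscore 72
            SimilarityEdge("b", "a", 95.0, 90.0, 1e-20),   # simscore 85.5
        ]
        g = build_similarity_graph(edges)
        assert g["a"]["b"]["weight"] == pytest.approx(85.5)

    def test_asymmetric_filtering_keeps_one_direction(self):
        edges = [
            SimilarityEdge("a", "b", 90.0, 95.0, 1e-20),
            SimilarityEdge("b", "a", 90.0, 60.0, 1e-20),  # fails coverage
        ]
        g = build_similarity_graph(edges)
        assert g.has_edge("a", "b")

    def test_evalue_filter_and_empty(self):
        assert build_similarity_graph([]).number_of_edges() == 0
        g = build_similarity_graph([SimilarityEdge("a", "b", 90.0, 90.0, 1e-3)])
        assert g.number_of_edges() == 0


def _mcl_oracle(weights, inflation=2.0, iters=200):
    """Hand-coded dense MCL iteration for cross-checking cluster counts."""
    M = np.array(weights, dtype=float)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(iters):
        M = M @ M
        M = M**inflation
        M /= M.sum(axis=0, keepdims=True)
    clusters = []
    for i in range(len(M)):
        if M[i, i] > 1e-6:
            members = frozenset(np.where(M[i] > 1e-6)[0])
            clusters.append(members)
    merged = []
    for c in clusters:
        hit = [m for m in merged if m & c]
        for m in hit:
            merged.remove(m)
            c = c | m
        merged.append(c)
    return merged


class TestMCL:
    def test_disjoint_triangles_two_clusters(self):
        g = nx.Graph()
        for offset in (0, 3):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(offset + i, offset + j, weight=1.0)
        clusters = mcl_cluster(g)
        assert sorted(len(c.member_ids) for c in clusters) == [3, 3]

    def test_isolated_node_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b", weight=1.0)
        clusters = mcl_cluster(g)
        assert {frozenset(c.member_ids) for c in clusters} == {
            frozenset({"solo"}),
            frozenset({"a", "b"}),
        }

    def _bridged_cliques(self):
        g = nx.Graph()
        for offset in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(offset + i, offset + j, weight=1.0)
        g.add_edge(3, 4, weight=0.1)
        return g

    def test_two_cliques_with_weak_bridge_split(self):
        g = self._bridged_cliques()
        clusters = mcl_cluster(g, inflation=2.0)
        assert len(clusters) == 2
        assert sorted(len(c.member_ids) for c in clusters) == [4, 4]
        # agrees with the independent dense-iteration oracle
        W = nx.to_numpy_array(g, nodelist=sorted(g.nodes()), weight="weight")
        assert len(_mcl_oracle(W)) == 2

    def test_partition_and_component_containment(self, small_community):
        from phameth.simulate import all_protein_edges

        edges = all_protein_edges(small_community)
        g = build_similarity_graph(edges)
        clusters = mcl_cluster(g)
        all_members = [m for c in clusters for m in c.member_ids]
        assert len(all_members) == len(set(all_members)) == g.number_of_nodes()
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for c in clusters:
            assert len({comp_of[m] for m in c.member_ids}) == 1

    def test_column_stochastic_every_iteration(self):
        g = self._bridged_cliques()
        sums = []
        mcl_cluster(g, on_iteration=lambda M: sums.append(M.sum(axis=0)))
        assert sums
        for s in sums:
            assert np.allclose(s, 1.0, atol=1e-9)

    def test_deterministic_under_relabeling(self):
        g = self._bridged_cliques()
        relabel = {n: f"x{9 - n}" for n in g.nodes()}
        g2 = nx.relabel_nodes(g, relabel)
        c1 = {frozenset(relabel[m] for m in c.member_ids) for c in mcl_cluster(g)}
        c2 = {frozenset(c.member_ids) for c in mcl_cluster(g2)}
        assert c1 == c2


class TestCategorise:
    def test_counts_and_fractions(self):
        from phameth.mtase import ProteinCluster

        clusters = [
            ProteinCluster(0, ("p1", "b1")),
            ProteinCluster(1, ("b2", "b3")),
            ProteinCluster(2, ("p2",)),
        ]
        origin = {"p1": "phage", "p2": "phage", "b1": "bacteria", "b2": "bacteria", "b3": "bacteria"}
        out = categorize_clusters(clusters, origin)
        assert out["counts"] == {"phage_only": 1, "bacteria_only": 1, "gene_sharing": 1}
        assert out["n_clusters"] == 3
        assert out["frac_phage_in_gene_sharing"] == pytest.approx(0.5)

    def test_all_phage_no_sharing(self):
        from phameth.mtase import ProteinCluster

        out = categorize_clusters(
            [ProteinCluster(0, ("p1", "p2"))], {"p1": "phage", "p2": "phage"}
        )
        assert out["counts"]["gene_sharing"] == 0

    def test_unlabeled_member_rejected(self):
        from phameth.mtase import ProteinCluster

        with pytest.raises(ValueError):
            categorize_clusters([ProteinCluster(0, ("p1",))], {})

    def test_planted_families_recovered(self, small_community):
        from phameth.simulate import all_protein_edges

        truth = small_community.truth.planted_cluster_ids
        edges = all_protein_edges(small_community)
        g = build_similarity_graph(edges)
        g.add_nodes_from(truth)
        clusters = mcl_cluster(g)
        # pairwise Rand index against the planted family labels
        label = {}
        for c in clusters:
            for m in c.member_ids:
                label[m] = c.cluster_id
        ids = sorted(truth)
        agree = total = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                same_truth = truth[ids[i]] == truth[ids[j]]
                same_pred = label[ids[i]] == label[ids[j]]
                agree += same_truth == same_pred
                total += 1
        assert agree / total >= 0.95
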