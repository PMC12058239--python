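"""Similarity networks, activity cliffs, embedding and hit selection."""

import networkx as nx
import numpy as np
import pytest

from augscreen.chem_core import Molecule, compute_fingerprint, parse_and_canonicalize, tanimoto
from augscreen.screening import (
    CliffPair,
    HitTable,
    ScreenResult,
    SimilarityNetwork,
    build_similarity_network,
    detect_activity_cliffs,
    embed_2d,
    pairwise_tanimoto,
    select_hits,
)


def _net_from_probs(edges, probs):
    g = nx.Graph()
    for node, p in probs.items():
        g.add_node(node, p=p)
    for i, j, w in edges:
        g.add_edge(i, j, weight=w)
    return SimilarityNetwork(graph=g, edge_threshold=0.5)


class TestNetwork:
    def test_identical_molecules_single_unit_edge(self):
        mols = [
            Molecule(id="a", smiles="CCO"),
            Molecule(id="b", smiles="CCO"),
        ]
        net = build_similarity_network(mols, [0.5, 0.6], edge_threshold=0.6)
        assert net.graph.number_of_edges() == 1
        assert net.graph["a"]["b"]["weight"] == 1.0
        assert not any(net.graph.has_edge(n, n) for n in net.graph)

    def test_matches_brute_force_construction(self, family, rng):
        mols = family[:60]
        probs = rng.random(len(mols))
        thr = 0.55
        net = build_similarity_network(mols, probs, edge_threshold=thr)
        fps = [compute_fingerprint(m) for m in mols]
        expected_edges = set()
        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                if tanimoto(fps[i], fps[j]) >= thr:
                    expected_edges.add(frozenset((mols[i].id, mols[j].id)))
        got_edges = {frozenset((i, j)) for i, j in net.graph.edges()}
        assert got_edges == expected_edges
        # degrees equal incident-edge counts
        for node, deg in net.degrees.items():
            assert deg == sum(1 for e in expected_edges if node in e)

    def test_unit_threshold_on_fingerprint_distinct_molecules_gives_no_edges(self):
        # note: chain homologs can share an identical ECFP bit *set*, so
        # "structurally distinct" is checked at the fingerprint level here
        smiles = ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "c1ccncc1", "C1CCCCC1", "CCOC", "CC#N"]
        mols = [Molecule(id=f"m{i}", smiles=s) for i, s in enumerate(smiles)]
        fps = [compute_fingerprint(m) for m in mols]
        assert len({f.bits for f in fps}) == len(mols)
        net = build_similarity_network(mols, [0.5] * len(mols), edge_threshold=1.0)
        assert net.graph.number_of_edges() == 0
        assert all(d == 0 for d in net.degrees.values())

    def test_threshold_validation(self, family):
        with pytest.raises(ValueError):
            build_similarity_network(family[:3], [0.1, 0.2, 0.3], edge_threshold=0.0)

    def test_probability_coverage_required(self, family):
        with pytest.raises(ValueError):
            build_similarity_network(family[:3], [0.1, 0.2], edge_threshold=0.5)

    def test_pairwise_tanimoto_symmetric_unit_diagonal(self, family):
        sim = pairwise_tanimoto(family[:30])
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)


class TestActivityCliffs:
    def test_hand_example(self):
        net = _net_from_probs([("a", "b", 0.8)], {"a": 0.9, "b": 0.2})
        cliffs = detect_activity_cliffs(net, cliff_delta=0.5)
        assert len(cliffs) == 1
        assert cliffs[0].delta_p == pytest.approx(0.7)

    def test_uniform_probabilities_give_none(self):
        net = _net_from_probs([("a", "b", 0.9), ("b", "c", 0.7)], {"a": 0.5, "b": 0.5, "c": 0.5})
        assert detect_activity_cliffs(net, cliff_delta=0.1) == []

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 12))
            nodes = [f"n{i}" for i in range(n)]
            probs = {v: float(rng.random()) for v in nodes}
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        edges.append((nodes[i], nodes[j], float(rng.random())))
            net = _net_from_probs(edges, probs)
            delta = float(rng.uniform(0.1, 0.8))
            expected = sum(1 for i, j, _ in edges if abs(probs[i] - probs[j]) >= delta)
            cliffs = detect_activity_cliffs(net, cliff_delta=delta)
            assert len(cliffs) == expected
            assert all(c.delta_p >= delta for c in cliffs)
            deltas = [c.delta_p for c in cliffs]
            assert deltas == sorted(deltas, reverse=True)


class TestEmbedding:
    def test_deterministic_under_seed(self, family):
        a = embed_2d(family[:30], perplexity=5, rng_seed=3)
        b = embed_2d(family[:30], perplexity=5, rng_seed=3)
        assert np.array_equal(a, b)

    def test_families_separate(self, family):
        other = [parse_and_canonicalize("C" * n + "N", id=f"amine{n}") for n in range(3, 23)]
        mols = family[:20] + other
        xy = embed_2d(mols, perplexity=6, rng_seed=0)
        a, b = xy[:20], xy[20:]
        intra = np.linalg.norm(a - a.mean(axis=0), axis=1).mean()
        inter = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        assert inter > intra

    def test_perplexity_must_be_less_than_n(self, family):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(family[:10], perplexity=30, rng_seed=0)
        with pytest.raises(ValueError):
            embed_2d(family[:4], perplexity=2, rng_seed=0)


class TestSelectHits:
    def _result(self, probs):
        mols = [Molecule(id=k, smiles="CCO") for k in probs]
        return ScreenResult(ids=list(probs), probs=np.array(list(probs.values())), molecules=mols)

    def test_boundary_cases(self):
        probs = {"sel": 0.85, "lowp": 0.65, "lowdeg": 0.9}
        net = _net_from_probs(
            [("sel", "lowp", 0.7), ("sel", "lowdeg", 0.7), ("sel", "x", 0.7), ("lowp", "x", 0.7),
             ("lowp", "lowdeg", 0.7), ("lowp", "y", 0.7)],
            {**probs, "x": 0.1, "y": 0.1},
        )
        res = self._result({**probs, "x": 0.1, "y": 0.1})
        hits = select_hits(res, net, prob_min=0.7, prob_max=1.0, min_degree=3)
        assert hits.ids == ["sel"]  # p 0.85, degree 3
        # p=0.65 rejected on probability despite degree; p=0.9 rejected on degree 2

    def test_monotone_in_thresholds(self, family, rng):
        mols = family[:50]
        probs = rng.random(50)
        net = build_similarity_network(mols, probs, edge_threshold=0.5)
        res = ScreenResult(ids=[m.id for m in mols], probs=probs, molecules=mols)
        strict = set(select_hits(res, net, prob_min=0.7, min_degree=3).ids)
        lower_p = set(select_hits(res, net, prob_min=0.5, min_degree=3).ids)
        lower_d = set(select_hits(res, net, prob_min=0.7, min_degree=1).ids)
        assert strict <= lower_p
        assert strict <= lower_d

    def test_inconsistent_ids_rejected(self, family):
        mols = family[:5]
        res = ScreenResult(ids=[m.id for m in mols], probs=np.full(5, 0.8), molecules=mols)
        net = _net_from_probs([], {"unrelated": 0.5})
        with pytest.raises(ValueError, match="cover"):
            select_hits(res, net)

    def test_criteria_recorded(self, family):
        mols = family[:5]
        probs = np.full(5, 0.8)
        net = build_similarity_network(mols, probs, edge_threshold=0.6)
        hits = select_hits(ScreenResult(ids=[m.id for m in mols], probs=probs, molecules=mols), net)
        assert hits.criteria["prob_min"] == 0.7
        assert hits.criteria["edge_threshold"] == 0.6
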