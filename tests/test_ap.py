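import numpy as np
import pytest

from netmark.ap import APConfig, ClusteringResult, cluster, net_similarity
from netmark.integration import SimilarityGraph

import oracles
from conftest import make_block_sims


def graph_from_dict(nodes, sim: dict, preference: float) -> SimilarityGraph:
    idx = {n: i for i, n in enumerate(nodes)}
    src = np.array([idx[i] for i, _ in sim])
    dst = np.array([idx[k] for _, k in sim])
    vals = np.array([sim[p] for p in sim], dtype=float)
    return SimilarityGraph(nodes=tuple(nodes), src=src, dst=dst, values=vals,
                           preference=preference)


class TestSmallFixtures:
    def test_two_genes_merge_when_preference_low(self):
        sims = graph_from_dict(
            ["g1", "g2"], {("g1", "g2"): 10.0, ("g2", "g1"): 10.0}, -100.0)
        res = cluster(sims, APConfig(seed=0))
        assert res.n_clusters == 1
        # exhaustive oracle agrees that one exemplar is optimal
        best, _ = oracles.best_exemplar_partition(
            ["g1", "g2"], {("g1", "g2"): 10.0, ("g2", "g1"): 10.0}, -100.0)
        assert net_similarity(sims, res) == pytest.approx(best, abs=1e-6)

    def test_dominant_preference_gives_singletons(self):
        sim = {("g1", "g2"): 1.0, ("g2", "g1"): 1.0,
               ("g2", "g3"): 1.0, ("g3", "g2"): 1.0}
        sims = graph_from_dict(["g1", "g2", "g3"], sim, 50.0)
        res = cluster(sims, APConfig(seed=0))
        assert res.n_clusters == 3
        assert all(e == g for g, e in res.exemplar_of.items())

    def test_two_triangles_recovered_exactly(self, rng):
        nodes = [f"n{i}" for i in range(6)]
        sim = {}
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for k in block:
                    if i != k:
                        sim[(nodes[i], nodes[k])] = 5.0
        sims = graph_from_dict(nodes, sim, -1.0)
        res = cluster(sims, APConfig(seed=1))
        members = sorted(sorted(m) for m in res.clusters.values())
        assert members == [["n0", "n1", "n2"], ["n3", "n4", "n5"]]
        best, _ = oracles.best_exemplar_partition(nodes, sim, -1.0)
        assert net_similarity(sims, res) == pytest.approx(best, abs=1e-6)


class TestOracleAgreement:
    def test_block_instances_reach_optimum(self, rng):
        """AP matches the exhaustive exemplar-set optimum on small blocks."""
        hits = 0
        trials = 25
        for trial in range(trials):
            n = int(rng.integers(4, 9))
            sims = make_block_sims(rng, n)
            res = cluster(sims, APConfig(seed=trial))
            value = net_similarity(sims, res)
            sim_dict = sims.as_dict()
            best, _ = oracles.best_exemplar_partition(sims.nodes, sim_dict,
                                                      sims.preference)
            assert value <= best + 1e-6  # never exceeds the optimum
            if value >= best - 1e-6:
                hits += 1
        assert hits >= int(0.9 * trials)


class TestResultContract:
    def test_partition_property_on_random_instances(self, rng):
        for trial in range(5):
            n = int(rng.integers(5, 12))
            nodes = [f"v{i}" for i in range(n)]
            sim = {}
            for i in range(n):
                for k in range(i + 1, n):
                    if rng.random() < 0.5:
                        v = float(rng.normal())
                        sim[(nodes[i], nodes[k])] = v
                        sim[(nodes[k], nodes[i])] = v
            if not sim:
                continue
            sims = graph_from_dict(nodes, sim, -0.5)
            res = cluster(sims, APConfig(seed=trial))
            # every clusterable node assigned exactly once
            assert sorted(res.exemplar_of) == sorted(sims.nodes)
            clusters = res.clusters
            all_members = [g for m in clusters.values() for g in m]
            assert sorted(all_members) == sorted(sims.nodes)
            for e in clusters:
                assert res.exemplar_of[e] == e

    def test_members_reach_their_exemplar(self, rng):
        """With the adjacent policy every member has a defined similarity to
        its exemplar (clusters are connected in the candidate graph)."""
        sims = make_block_sims(rng, 8)
        res = cluster(sims, APConfig(seed=3))
        table = sims.as_dict()
        for g, e in res.exemplar_of.items():
            assert g == e or (g, e) in table

    def test_determinism(self, rng):
        sims = make_block_sims(rng, 7)
        r1 = cluster(sims, APConfig(seed=11))
        r2 = cluster(sims, APConfig(seed=11))
        assert r1.exemplar_of == r2.exemplar_of
        assert r1.iterations == r2.iterations

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            APConfig(damping=0.4)
        with pytest.raises(ValueError):
            APConfig(max_iter=10, conv_window=20)

    def test_inconsistent_exemplar_map_rejected(self):
        with pytest.raises(ValueError):
            ClusteringResult(exemplar_of={"a": "b", "b": "c", "c": "c"},
                             iterations=1, converged=True)


class TestNetSimilarity:
    def test_all_singletons_scores_n_times_preference(self, rng):
        sims = make_block_sims(rng, 6, preference=-2.0)
        singletons = ClusteringResult(
            exemplar_of={n: n for n in sims.nodes}, iterations=1,
            converged=True)
        assert net_similarity(sims, singletons) == pytest.approx(-12.0)

    def test_hand_summed_three_gene_fixture(self):
        sim = {("a", "b"): 4.0, ("b", "a"): 3.0,
               ("c", "b"): 2.0, ("b", "c"): 1.0}
        sims = graph_from_dict(["a", "b", "c"], sim, -1.0)
        res = ClusteringResult(exemplar_of={"a": "b", "b": "b", "c": "b"},
                               iterations=1, converged=True)
        # s(a,b) + c + s(c,b) = 4 - 1 + 2
        assert net_similarity(sims, res) == pytest.approx(5.0)

    def test_absent_assignment_is_minus_inf(self):
        sim = {("a", "b"): 4.0, ("b", "a"): 3.0}
        sims = graph_from_dict(["a", "b", "c"], sim | {("c", "b"): 0.5,
                                                       ("b", "c"): 0.5}, -1.0)
        res = ClusteringResult(exemplar_of={"a": "c", "b": "c", "c": "c"},
                               iterations=1, converged=True)
        assert net_similarity(sims, res) == -np.inf


def test_exemplar_count_monotone_in_preference(rng):
    """Raising the preference never removes exemplars on a fixed fixture."""
    sims = make_block_sims(rng, 8, preference=0.0)
    counts = []
    for c in (-50.0, -10.0, -1.0, 2.0, 20.0):
        res = cluster(sims.with_preference(c), APConfig(seed=5))
        counts.append(res.n_clusters)
    assert counts == sorted(counts)
    assert counts[-1] == 8  # dominant preference -> all singletons


def test_matches_sklearn_on_dense_instance(rng):
    """Independent cross-check against scikit-learn's dense implementation
    with an explicitly fixed preference."""
    from sklearn.cluster import AffinityPropagation

    n = 12
    x = rng.normal(size=(n, 2))
    x[: n // 2] += 4.0
    S = -((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    pref = -8.0
    nodes = [f"p{i}" for i in range(n)]
    sim = {(nodes[i], nodes[k]): float(S[i, k])
           for i in range(n) for k in range(n) if i != k}
    sims = graph_from_dict(nodes, sim, pref)
    res = cluster(sims, APConfig(seed=0, damping=0.7))

    Sd = S.copy()
    np.fill_diagonal(Sd, pref)
    skl = AffinityPropagation(affinity="precomputed", preference=pref,
                              damping=0.7, max_iter=2000,
                              convergence_iter=50, random_state=0).fit(Sd)
    mine = [frozenset(m) for m in res.clusters.values()]
    theirs = {}
    for i, lab in enumerate(skl.labels_):
        theirs.setdefault(lab, set()).add(nodes[i])
    assert sorted(map(sorted, mine)) == sorted(
        sorted(m) for m in theirs.values())
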