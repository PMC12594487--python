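import numpy as np
import pytest

from dynstates import (
    HMGM,
    build_hmgm,
    cluster_layers,
    cluster_regions,
    consensus_communities,
    fractional_membership,
    genlouvain_optimize,
    make_ground_truth,
    multilayer_modularity,
    stationary_distribution,
)
from dynstates.compare import ami
from dynstates.hmm import FittedStateModel
from dynstates.multilayer import SpatiotemporalPartition, _modularity_matrix


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_modularity(hmgm, labels, gamma, coupling_scale=1.0):
    """Double-loop evaluation of the multilayer Newman-Girvan formula,
    written independently of the vectorized kernel."""
    K, D = hmgm.n_layers, hmgm.n_nodes
    omega = coupling_scale * hmgm.coupling
    two_mu = 0.0
    for s in range(K):
        two_mu += hmgm.layers[s].sum()
    for i in range(D):
        for s in range(K):
            for r in range(K):
                if s != r:
                    two_mu += omega[s, r]
    total = 0.0
    for s in range(K):
        A = hmgm.layers[s]
        k = A.sum(axis=1)
        two_m = k.sum()
        if two_m > 0:
            for i in range(D):
                for j in range(D):
                    if labels[i, s] == labels[j, s]:
                        total += A[i, j] - gamma * k[i] * k[j] / two_m
    for i in range(D):
        for s in range(K):
            for r in range(K):
                if s != r and labels[i, s] == labels[i, r]:
                    total += omega[s, r]
    return total / two_mu


def partitions_of(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, m):
        if i == n:
            yield labels.copy()
            return
        for c in range(m + 1):
            labels[i] = c
            yield from rec(i + 1, max(m, c + 1))

    yield from rec(1, 1) if n > 1 else iter([np.zeros(1, dtype=int)])


def exhaustive_optimum(hmgm, gamma, coupling_scale=1.0):
    B, two_mu = _modularity_matrix(hmgm, gamma, coupling_scale)
    n = B.shape[0]
    best = -np.inf
    for flat in partitions_of(n):
        q = B[flat[:, None] == flat[None, :]].sum() / two_mu
        best = max(best, q)
    return best


def random_toy_hmgm(rng, D, K):
    layers = []
    for _ in range(K):
        M = rng.uniform(size=(D, D))
        A = np.triu(M, 1)
        A = A + A.T
        layers.append(A)
    M = rng.uniform(size=(K, K))
    omega = np.triu(M, 1) * 0.3
    omega = omega + omega.T
    return HMGM(layers=np.stack(layers), coupling=omega, pi=np.full(K, 1 / K))


def two_clique_layer(n_per=3):
    D = 2 * n_per
    A = np.zeros((D, D))
    A[:n_per, :n_per] = 1
    A[n_per:, n_per:] = 1
    np.fill_diagonal(A, 0)
    return A


# ---------------------------------------------------------------------------


class TestBuildHmgm:
    def _model(self, cov, P):
        K = P.shape[0]
        return FittedStateModel(
            means=np.zeros((K, 2)),
            covariances=np.stack([np.eye(2)] * K),
            transition_matrix=P,
            initial_distribution=stationary_distribution(P),
            roi_means=np.zeros((K, cov.shape[1])),
            roi_covariances=cov,
        )

    def test_identity_covariance_gives_empty_layer(self):
        P = np.full((2, 2), 0.5)
        model = self._model(np.stack([np.eye(3)] * 2), P)
        g = build_hmgm(model)
        assert np.all(g.layers == 0)

    def test_perfect_correlation_gives_unit_edge(self):
        C = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        C = C + 1e-9 * np.eye(3)
        P = np.full((2, 2), 0.5)
        g = build_hmgm(self._model(np.stack([C, np.eye(3)]), P))
        assert g.layers[0, 0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_coupling_is_symmetrized_transition(self):
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        g = build_hmgm(self._model(np.stack([np.eye(2)] * 2), P), coupling_scale=1.0)
        assert g.coupling[0, 1] == pytest.approx(0.3)
        assert g.coupling[0, 0] == 0.0


class TestMultilayerModularity:
    def test_two_cliques_closed_form(self):
        """Newman-Girvan Q of two equal disconnected cliques at the true
        split is exactly 1/2."""
        g = HMGM(layers=two_clique_layer()[None], coupling=np.zeros((1, 1)), pi=np.ones(1))
        labels = np.repeat([0, 1], 3)[:, None]
        assert multilayer_modularity(g, labels, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_is_zero(self):
        g = HMGM(layers=two_clique_layer()[None], coupling=np.zeros((1, 1)), pi=np.ones(1))
        labels = np.zeros((6, 1), dtype=int)
        assert multilayer_modularity(g, labels, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_toys(self, rng):
        """Vectorized kernel equals the double-loop formula to 1e-12."""
        for _ in range(20):
            D, K = int(rng.integers(2, 4)), int(rng.integers(2, 4))
            g = random_toy_hmgm(rng, D, K)
            labels = rng.integers(0, 3, size=(D, K))
            q_fast = multilayer_modularity(g, labels, 1.1, 0.7)
            q_slow = brute_force_modularity(g, labels, 1.1, 0.7)
            assert q_fast == pytest.approx(q_slow, abs=1e-12)


class TestGenLouvain:
    def test_planted_two_communities_recovered(self):
        """Two cliques replicated over 2 coupled layers split correctly."""
        A = two_clique_layer()
        omega = np.array([[0.0, 0.4], [0.4, 0.0]])
        g = HMGM(layers=np.stack([A, A]), coupling=omega, pi=np.full(2, 0.5))
        planted = np.repeat(np.repeat([0, 1], 3)[:, None], 2, axis=1)
        for seed in range(10):
            part = genlouvain_optimize(g, 1.0, seed=seed)
            assert ami(part.labels.reshape(-1), planted.reshape(-1)) == 1.0

    def test_attains_exhaustive_optimum_on_toys(self, rng):
        """Louvain never exceeds, and usually attains, the global optimum."""
        attained = 0
        trials = 12
        for t in range(trials):
            g = random_toy_hmgm(rng, 4, 2)  # 8 node-layers
            opt = exhaustive_optimum(g, 1.0)
            part = genlouvain_optimize(g, 1.0, seed=t)
            assert part.Q <= opt + 1e-9
            attained += part.Q >= opt - 1e-9
        assert attained >= int(0.75 * trials)

    def test_huge_resolution_isolates_nodes(self):
        g = HMGM(layers=two_clique_layer()[None], coupling=np.zeros((1, 1)), pi=np.ones(1))
        part = genlouvain_optimize(g, 1e3, seed=0)
        assert part.n_communities == 6

    def test_deterministic_given_seed(self, rng):
        g = random_toy_hmgm(rng, 5, 3)
        a = genlouvain_optimize(g, 1.0, seed=42)
        b = genlouvain_optimize(g, 1.0, seed=42)
        assert np.array_equal(a.labels, b.labels)


class TestConsensus:
    def _planted_hmgm(self, seed, D=16, K=3):
        gt = make_ground_truth(K, D, block_sizes=[D // 2, D // 2], seed=seed)
        layers = []
        for k in range(K):
            C = gt.covariances[k]
            sd = np.sqrt(np.diag(C))
            A = np.abs(C / np.outer(sd, sd))
            np.fill_diagonal(A, 0)
            layers.append(A)
        P = gt.transition_matrix
        omega = 0.5 * (P + P.T)
        np.fill_diagonal(omega, 0)
        return HMGM(layers=np.stack(layers), coupling=omega,
                    pi=stationary_distribution(P)), gt

    def test_recovers_planted_blocks(self):
        g, gt = self._planted_hmgm(seed=0)
        part, coclass = consensus_communities(
            g, resolution_grid=[0.9, 1.0, 1.1], coupling_grid=[0.5, 1.0],
            n_runs=8, seed=1)
        assert ami(part.labels.reshape(-1), gt.planted_labels.reshape(-1)) >= 0.9
        assert np.allclose(coclass, coclass.T)
        assert np.allclose(np.diag(coclass), 1.0)

    def test_unanimous_runs_return_that_partition(self):
        """When every run agrees, consensus equals the common partition."""
        A = two_clique_layer()
        g = HMGM(layers=A[None], coupling=np.zeros((1, 1)), pi=np.ones(1))
        part, coclass = consensus_communities(
            g, resolution_grid=[1.0], coupling_grid=[1.0], n_runs=5, seed=0)
        assert ami(part.labels[:, 0], np.repeat([0, 1], 3)) == 1.0
        assert set(np.unique(coclass)) <= {0.0, 1.0}

    def test_zero_coupling_equals_per_layer_consensus(self):
        """With omega = 0 the multilayer machinery reduces to independent
        single-layer consensus partitions."""
        g, _ = self._planted_hmgm(seed=3, D=12, K=2)
        g0 = HMGM(layers=g.layers, coupling=np.zeros_like(g.coupling), pi=g.pi)
        part, _ = consensus_communities(
            g0, resolution_grid=[1.0], coupling_grid=[1.0], n_runs=6, seed=4)
        for s in range(g0.n_layers):
            single = HMGM(layers=g0.layers[s][None], coupling=np.zeros((1, 1)),
                          pi=np.ones(1))
            sp, _ = consensus_communities(
                single, resolution_grid=[1.0], coupling_grid=[1.0], n_runs=6, seed=4)
            assert ami(part.labels[:, s], sp.labels[:, 0]) == pytest.approx(1.0)

    def test_consensus_not_worse_than_mean_run(self):
        g, _ = self._planted_hmgm(seed=5)
        qs = [genlouvain_optimize(g, 1.0, seed=s).Q for s in range(6)]
        part, _ = consensus_communities(
            g, resolution_grid=[1.0], coupling_grid=[1.0], n_runs=6, seed=6)
        assert part.Q >= np.mean(qs) - 1e-9

    def test_static_memberships_for_aligned_blocks(self):
        """Layer-stable planted communities give near-unit fractional
        membership maxima; per-layer shuffled blocks give lower maxima."""
        g_static, _ = self._planted_hmgm(seed=7)
        gt_shuf = make_ground_truth(
            3, 16, block_sizes=[8, 8], seed=7, shuffle_blocks_per_state=True)
        layers = []
        for k in range(3):
            C = gt_shuf.covariances[k]
            A = np.abs(C / np.outer(np.sqrt(np.diag(C)), np.sqrt(np.diag(C))))
            np.fill_diagonal(A, 0)
            layers.append(A)
        omega = 0.5 * (gt_shuf.transition_matrix + gt_shuf.transition_matrix.T)
        np.fill_diagonal(omega, 0)
        g_shuf = HMGM(layers=np.stack(layers), coupling=omega,
                      pi=stationary_distribution(gt_shuf.transition_matrix))
        maxima = {}
        for name, g in [("static", g_static), ("shuffled", g_shuf)]:
            part, _ = consensus_communities(
                g, resolution_grid=[1.0], coupling_grid=[1.0], n_runs=8, seed=8)
            F = fractional_membership(part, g.pi)
            maxima[name] = F.max(axis=1).mean()
        assert maxima["static"] > maxima["shuffled"]


class TestFractionalMembership:
    def test_static_region_has_unit_membership(self):
        labels = np.zeros((4, 3), dtype=int)
        part = SpatiotemporalPartition(labels=labels)
        F = fractional_membership(part, np.array([0.5, 0.3, 0.2]))
        assert np.allclose(F, 1.0)

    def test_weighted_count(self):
        labels = np.array([[0, 1]])  # one ROI, community 0 in layer 1, 1 in layer 2
        part = SpatiotemporalPartition(labels=labels)
        F = fractional_membership(part, np.array([0.75, 0.25]))
        assert np.allclose(F, [[0.75, 0.25]])

    def test_rows_sum_to_one(self, rng):
        labels = rng.integers(0, 3, size=(7, 4))
        part = SpatiotemporalPartition(labels=labels)
        F = fractional_membership(part, np.full(4, 0.25))
        assert np.allclose(F.sum(axis=1), 1.0, atol=1e-12)


class TestLayerClustering:
    def test_identical_layers_merge_first(self):
        labels = np.array([[0, 0, 2], [0, 0, 2], [1, 1, 0], [1, 1, 1]])
        Z, flat, Dm = cluster_layers(SpatiotemporalPartition(labels=labels), 2)
        assert Dm[0, 1] == 0.0
        assert flat[0] == flat[1] != flat[2]

    def test_disjoint_pairs_give_zero_jaccard(self):
        labels = np.array([[0, 0], [0, 1], [1, 1], [1, 0]])
        _, _, Dm = cluster_layers(SpatiotemporalPartition(labels=labels), 2)
        assert Dm[0, 1] == 1.0  # Jaccard 0 -> distance 1

    def test_odd_layer_separated(self):
        labels = np.array([[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]])
        _, flat, _ = cluster_layers(SpatiotemporalPartition(labels=labels), 2)
        assert flat[0] == flat[1] != flat[2]

    def test_region_clustering_transposed(self):
        labels = np.array([[0, 0], [0, 0], [1, 1]])
        _, flat, _ = cluster_regions(SpatiotemporalPartition(labels=labels), 2)
        assert flat[0] == flat[1]
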