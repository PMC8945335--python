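import itertools

import networkx as nx
import numpy as np
import pytest

from issrpop.marker_data import MarkerMatrix
from issrpop.structure_inference import (
    AdmixtureRun,
    DistanceMatrix,
    admixture_mcmc,
    dapc,
    evanno,
    hamming_distances,
    minimum_spanning_network,
    pca,
)
from issrpop.synthetic_data import SimDesign, generate


def _matrix(rows, pops=None):
    rows = np.asarray(rows)
    ids = [f"i{k}" for k in range(rows.shape[0])]
    loci = [f"L{j}" for j in range(rows.shape[1])]
    pops = pops or ["A"] * rows.shape[0]
    return MarkerMatrix(ids, loci, rows, dict(zip(ids, pops)))


class TestHamming:
    def test_identical_and_complementary(self):
        rows = np.vstack([np.ones(10), np.ones(10), np.zeros(10)]).astype(int)
        d = hamming_distances(_matrix(rows))
        assert d.values[0, 1] == 0
        assert d.values[0, 2] == 10

    def test_matches_brute_force_xor(self):
        rng = np.random.default_rng(12)
        rows = (rng.random((6, 9)) < 0.5).astype(int)
        d = hamming_distances(_matrix(rows)).values
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(int((rows[i] != rows[j]).sum()))


class TestMSN:
    @staticmethod
    def _exhaustive_mst_weight(w):
        n = w.shape[0]
        best = np.inf
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for combo in itertools.combinations(edges, n - 1):
            g = nx.Graph(combo)
            if g.number_of_nodes() == n and nx.is_connected(g):
                best = min(best, sum(w[i, j] for i, j in combo))
        return best

    def test_two_nodes_single_edge(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        net = minimum_spanning_network(d)
        assert net.edges == [("a", "b", 2.0)]

    def test_unique_weights_match_exhaustive_search(self):
        rng = np.random.default_rng(3)
        n = 5
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.permutation(len(iu[0])) + 1.0
        w = w + w.T
        net = minimum_spanning_network(DistanceMatrix([f"n{i}" for i in range(n)], w))
        mst_edges = net.edges[: n - 1]
        total = sum(e[2] for e in mst_edges)
        assert total == pytest.approx(self._exhaustive_mst_weight(w))
        assert len(net.edges) == n - 1  # unique weights: no tied extras

    def test_equidistant_triangle_keeps_cycle(self):
        w = np.full((3, 3), 1.0)
        np.fill_diagonal(w, 0.0)
        net = minimum_spanning_network(DistanceMatrix(["a", "b", "c"], w))
        assert len(net.edges) == 3  # tie retention: full 3-cycle

    def test_spanning_and_connected(self):
        rng = np.random.default_rng(5)
        rows = (rng.random((8, 12)) < 0.5).astype(int)
        m = _matrix(rows)
        net = minimum_spanning_network(hamming_distances(m))
        g = nx.Graph((u, v) for u, v, _ in net.edges)
        assert nx.is_connected(g)
        assert g.number_of_nodes() == 8
        assert len(net.edges) >= 7


class TestPCA:
    def test_single_variable_locus_carries_all_variance(self):
        rows = np.zeros((6, 4), dtype=int)
        rows[:3, 0] = 1
        res = pca(_matrix(rows))
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_three_by_three_closed_form_eigenvalues(self):
        # bands [[1,0,0],[0,1,0],[1,1,1]]: covariance eigenvalues are
        # {1/2, 1/2, 0} (characteristic polynomial solved symbolically)
        res = pca(_matrix([[1, 0, 0], [0, 1, 0], [1, 1, 1]]))
        assert sorted(res.eigenvalues, reverse=True) == pytest.approx(
            [0.5, 0.5, 0.0], abs=1e-12
        )

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(9)
        rows = (rng.random((10, 7)) < 0.4).astype(int)
        m = _matrix(rows)
        res = pca(m)
        X = rows - rows.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - X).max() < 1e-8

    def test_constant_matrix_no_crash(self):
        res = pca(_matrix(np.ones((4, 3), dtype=int)))
        assert np.allclose(res.eigenvalues, 0)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((12, 9)) < 0.5).astype(int)
        res = pca(_matrix(rows))
        S = res.scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestDAPC:
    def test_two_separated_clusters_recovered(self):
        hits = 0
        rng = np.random.default_rng(0)
        for rep in range(20):
            a = (rng.random((15, 30)) < 0.9).astype(int)
            b = (rng.random((15, 30)) < 0.1).astype(int)
            m = _matrix(np.vstack([a, b]))
            res = dapc(m, seed=rep, k_max=6)
            hits += res.k == 2
        assert hits >= 18  # >= 90% of runs

    def test_k_one_means_no_discriminant_functions(self):
        rng = np.random.default_rng(1)
        m = _matrix((rng.random((8, 10)) < 0.5).astype(int))
        res = dapc(m, k=1)
        assert res.k == 1
        assert res.scores.shape[1] == 0
        assert res.assignments.nunique() == 1

    def test_k_larger_than_n_rejected(self):
        m = _matrix(np.eye(3, dtype=int))
        with pytest.raises(ValueError):
            dapc(m, k=10)

    def test_function_count_bounded_by_k_minus_one(self):
        rng = np.random.default_rng(6)
        m = _matrix((rng.random((20, 15)) < 0.5).astype(int))
        res = dapc(m, k=3, seed=0)
        assert res.scores.shape[1] <= 2


class TestAdmixture:
    def test_k_one_trivial_membership(self):
        rng = np.random.default_rng(0)
        m = _matrix((rng.random((6, 8)) < 0.5).astype(int))
        run = admixture_mcmc(m, K=1, n_burnin=50, n_sample=50, seed=1)
        assert np.allclose(run.Q.to_numpy(), 1.0)

    def test_q_rows_sum_to_one(self):
        m, _ = generate(SimDesign(n_pops=2, n_per_pop=8, n_loci=20, seed=4))
        run = admixture_mcmc(m, K=3, n_burnin=200, n_sample=400, seed=2)
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_fixed_opposite_populations_concentrate(self):
        bands = np.vstack([np.ones((10, 30)), np.zeros((10, 30))]).astype(int)
        m = _matrix(bands, ["A"] * 10 + ["B"] * 10)
        run = admixture_mcmc(m, K=2, n_burnin=500, n_sample=1000, seed=3)
        qa = run.Q.iloc[:10].mean().max()
        qb = run.Q.iloc[10:].mean().max()
        assert qa > 0.95 and qb > 0.95
        # opposite populations claim different clusters
        assert run.Q.iloc[:10].mean().idxmax() != run.Q.iloc[10:].mean().idxmax()

    def test_k_exceeding_individuals_rejected(self):
        m = _matrix(np.eye(3, dtype=int))
        with pytest.raises(ValueError):
            admixture_mcmc(m, K=5, n_burnin=10, n_sample=10)

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        m = _matrix((rng.random((8, 12)) < 0.5).astype(int))
        a = admixture_mcmc(m, K=2, n_burnin=100, n_sample=100, seed=9)
        b = admixture_mcmc(m, K=2, n_burnin=100, n_sample=100, seed=9)
        assert a.loglik == b.loglik
        assert np.array_equal(a.Q.to_numpy(), b.Q.to_numpy())


def _runs_from_table(means, jitter=1.0):
    runs = []
    for k, mu in means.items():
        for delta in (-jitter, jitter):
            runs.append(AdmixtureRun(K=k, seed=0, loglik=mu + delta, Q=None, theta=None))
    return runs


class TestEvanno:
    def test_linear_likelihood_gives_zero_delta_k(self):
        runs = _runs_from_table({1: -1000.0, 2: -900.0, 3: -800.0, 4: -700.0})
        ev = evanno(runs)
        interior = ev.table["deltaK"].dropna()
        assert np.allclose(interior, 0.0)

    def test_hand_table_arithmetic(self):
        # means {-1000, -600, -580, -575}, reps +-1 (sd = sqrt(2)):
        # L'(2)=400, L'(3)=20, L'(4)=5; |L''(2)|=380, |L''(3)|=15;
        # deltaK(2)=380/sqrt(2)=268.7006, deltaK(3)=15/sqrt(2)=10.6066
        runs = _runs_from_table({1: -1000.0, 2: -600.0, 3: -580.0, 4: -575.0})
        ev = evanno(runs)
        assert ev.table.loc[2, "deltaK"] == pytest.approx(268.70057685088807)
        assert ev.table.loc[3, "deltaK"] == pytest.approx(10.606601717798211)
        assert ev.best_k == 2

    def test_zero_sd_yields_inf_sentinel(self):
        runs = _runs_from_table({1: -100.0, 2: -50.0, 3: -40.0, 4: -39.0}, jitter=0.0)
        with pytest.warns(UserWarning, match="inf"):
            ev = evanno(runs)
        assert np.isinf(ev.table.loc[2, "deltaK"])

    def test_requires_consecutive_ks_and_replicates(self):
        with pytest.raises(ValueError):
            evanno(_runs_from_table({1: -10.0, 3: -5.0, 4: -4.0}))
        runs = _runs_from_table({1: -10.0, 2: -8.0, 3: -7.0})[::2]  # 1 rep each
        with pytest.raises(ValueError):
            evanno(runs)
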