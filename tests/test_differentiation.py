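import itertools

import numpy as np
import pandas as pd
import pytest

from issrpop.marker_data import MarkerMatrix, PopulationGeo
from issrpop.diversity import estimate_freqs
from issrpop.differentiation import (
    amova_binary,
    gene_flow_crow_aoki,
    mantel_ibd,
    nei_gst,
    pairwise_fst,
)


def _matrix(rows, pops):
    rows = np.asarray(rows)
    ids = [f"i{k}" for k in range(rows.shape[0])]
    loci = [f"L{j}" for j in range(rows.shape[1])]
    return MarkerMatrix(ids, loci, rows, dict(zip(ids, pops)))


class TestGst:
    def test_identical_frequencies_zero(self):
        block = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        m = _matrix(np.vstack([block, block]), ["A"] * 4 + ["B"] * 4)
        assert nei_gst(estimate_freqs(m)).gst == pytest.approx(0.0, abs=1e-12)

    def test_opposite_fixation_gives_one(self):
        bands = np.vstack([np.ones((10, 3)), np.zeros((10, 3))]).astype(int)
        m = _matrix(bands, ["A"] * 10 + ["B"] * 10)
        res = nei_gst(estimate_freqs(m))
        assert res.hs == pytest.approx(0.0)
        assert res.ht == pytest.approx(0.5)
        assert res.gst == pytest.approx(1.0)

    def test_all_monomorphic_rejected(self):
        m = _matrix(np.ones((8, 3), dtype=int), ["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError, match="monomorphic"):
            nei_gst(estimate_freqs(m))


class TestAmova:
    @staticmethod
    def _oracle(m):
        """Independent AMOVA oracle: sums of squares via deviations from
        group centroids (not the pairwise-distance route the module uses)."""
        X = m.bands.astype(float)
        labels = m.pop_labels
        pops = m.populations
        centroid = X.mean(axis=0)
        ss_total = ((X - centroid) ** 2).sum()
        ss_within = 0.0
        for p in pops:
            sub = X[labels == p]
            ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
        ss_among = ss_total - ss_within
        N, g = X.shape[0], len(pops)
        n_g = np.array([(labels == p).sum() for p in pops], dtype=float)
        n0 = (N - (n_g**2).sum() / N) / (g - 1)
        msw = ss_within / (N - g)
        msa = ss_among / (g - 1)
        s2w = msw
        s2a = (msa - msw) / n0
        return ss_among, ss_within, s2a, s2w

    def test_components_match_centroid_oracle(self, amova_toy):
        ss_among, ss_within, s2a, s2w = self._oracle(amova_toy)
        res = amova_binary(amova_toy, n_perm=0)
        assert res.ss_among == pytest.approx(ss_among, abs=1e-10)
        assert res.ss_within == pytest.approx(ss_within, abs=1e-10)
        assert res.sigma2_among == pytest.approx(s2a, abs=1e-10)
        assert res.sigma2_within == pytest.approx(s2w, abs=1e-10)
        assert res.phi_st == pytest.approx(s2a / (s2a + s2w), abs=1e-10)

    def test_percentages_sum_to_hundred(self, amova_toy, three_pop_matrix):
        for m in (amova_toy, three_pop_matrix):
            res = amova_binary(m, n_perm=0)
            assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_exchangeable_null(self):
        block = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1], [0, 0, 0]])
        m = _matrix(np.vstack([block, block]), ["A"] * 4 + ["B"] * 4)
        res = amova_binary(m, n_perm=200, seed=1)
        assert res.phi_st <= 0.0 + 1e-9
        assert res.p_value > 0.5

    def test_singleton_population_rejected(self):
        m = _matrix([[1, 0], [0, 1], [1, 1]], ["A", "A", "B"])
        with pytest.raises(ValueError, match="single individual"):
            amova_binary(m, n_perm=0)

    def test_permutation_determinism(self, amova_toy):
        a = amova_binary(amova_toy, n_perm=200, seed=5)
        b = amova_binary(amova_toy, n_perm=200, seed=5)
        assert a.p_value == b.p_value


class TestCrowAoki:
    def test_full_differentiation_no_flow(self):
        assert gene_flow_crow_aoki(1.0, 6) == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        # Gst = 0.25, n = 6: alpha = (6/5)^2 = 1.44, Nm = 3/5.76
        assert gene_flow_crow_aoki(0.25, 6) == pytest.approx(0.5208333333333334)

    def test_zero_gst_rejected(self):
        with pytest.raises(ValueError):
            gene_flow_crow_aoki(0.0, 6)


class TestPairwiseFst:
    def test_duplicate_populations_near_zero(self):
        block = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        m = _matrix(np.vstack([block, block]), ["A"] * 4 + ["B"] * 4)
        res = pairwise_fst(m)
        assert res.pairwise_fst.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)
        assert res.linearized.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)

    def test_linearization_closed_form(self):
        assert 0.5 / (1 - 0.5) == pytest.approx(1.0)

    def test_matches_per_pair_amova(self, three_pop_matrix):
        res = pairwise_fst(three_pop_matrix)
        pops = three_pop_matrix.populations
        for a, b in itertools.combinations(pops, 2):
            sub = three_pop_matrix.subset(keep_populations=[a, b])
            expected = max(amova_binary(sub, n_perm=0).phi_st, 0.0)
            assert res.pairwise_fst.loc[a, b] == pytest.approx(expected, abs=1e-12)
        m = res.pairwise_fst.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)


class TestMantel:
    @staticmethod
    def _setup(seed=0):
        rng = np.random.default_rng(seed)
        pops = ["A", "B", "C", "D"]
        geo = PopulationGeo({p: tuple(rng.uniform(0, 10, 2)) for p in pops})
        g = rng.uniform(0.1, 2.0, (4, 4))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        return pd.DataFrame(g, index=pops, columns=pops), geo

    @staticmethod
    def _exhaustive_p(gen, geo):
        pops = list(gen.index)
        D = geo.distance_matrix(order=pops).to_numpy()
        np.fill_diagonal(D, 1.0)
        D = np.log10(D)
        G = gen.to_numpy()
        iu = np.triu_indices(len(pops), 1)
        r_obs = np.corrcoef(D[iu], G[iu])[0, 1]
        hits = 0
        perms = list(itertools.permutations(range(len(pops))))
        for perm in perms:
            Gp = G[np.ix_(perm, perm)]
            hits += np.corrcoef(D[iu], Gp[iu])[0, 1] >= r_obs - 1e-12
        return hits / len(perms)

    def test_monte_carlo_within_two_se_of_exhaustive(self):
        gen, geo = self._setup(3)
        p_exact = self._exhaustive_p(gen, geo)
        n_perm = 3000
        res = mantel_ibd(gen, geo, n_perm=n_perm, seed=11, n_boot=0)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p - p_exact) <= 2 * se + 1 / n_perm

    def test_perfect_monotone_association(self):
        pops = ["A", "B", "C", "D", "E"]
        geo = PopulationGeo({p: (float(2**k), 0.0) for k, p in enumerate(pops)})
        d = geo.distance_matrix()
        gen = np.log10(d.where(d > 0, 1.0)) ** 3  # monotone transform
        gen = gen - np.diag(np.diag(gen))
        res = mantel_ibd(pd.DataFrame(gen, index=pops, columns=pops), geo,
                         n_perm=500, seed=0, n_boot=0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_matches_skbio_statistic(self):
        """Cross-check the Mantel r against an independent implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        gen, geo = self._setup(8)
        pops = list(gen.index)
        res = mantel_ibd(gen, geo, n_perm=100, seed=0, n_boot=0)
        logd = geo.distance_matrix(order=pops).to_numpy()
        np.fill_diagonal(logd, 1.0)
        logd = np.log10(logd)
        np.fill_diagonal(logd, 0)
        r, p, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(logd, ids=pops),
            skbio_stats.DistanceMatrix(gen.to_numpy(), ids=pops),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_zero_distance_rejected(self):
        gen, _ = self._setup(1)
        geo = PopulationGeo({"A": (0, 0), "B": (0, 0), "C": (1, 1), "D": (2, 2)})
        with pytest.raises(ValueError, match="zero"):
            mantel_ibd(gen, geo, n_perm=10)
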