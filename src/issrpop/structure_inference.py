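"""Population-structure inference for binary band data.

Covers the multivariate toolkit (Hamming distances, minimum spanning
network, covariance PCA, DAPC with k-means/BIC group selection) and a
model-based route: a Gibbs-sampled Bayesian admixture model for dominant
band phenotypes with replicate runs summarised by the Evanno ΔK statistic
to choose the number of clusters.

The admixture model treats the band itself as the Bernoulli observable
(cluster-specific band frequencies), a deliberate simplification of
genotype-based admixture programs that is adequate for recovering cluster
membership from dominant data at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._gibbs import gibbs_admixture
from .marker_data import MarkerMatrix

__all__ = [
    "DistanceMatrix",
    "NetworkResult",
    "OrdinationResult",
    "DapcResult",
    "AdmixtureRun",
    "EvannoTable",
    "hamming_distances",
    "minimum_spanning_network",
    "pca",
    "dapc",
    "admixture_mcmc",
    "evanno",
]


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray
    metric: str = "hamming"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class NetworkResult:
    """Minimum spanning network: MST edges plus tied alternatives."""

    nodes: list  # (individual, population)
    edges: list  # (u, v, weight); MST edges first
    is_spanning: bool = True

    def total_mst_weight(self) -> float:
        g = nx.Graph()
        g.add_weighted_edges_from(self.edges)
        t = nx.minimum_spanning_tree(g)
        return float(sum(d["weight"] for *_, d in t.edges(data=True)))


@dataclass
class OrdinationResult:
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    loadings: pd.DataFrame


@dataclass
class DapcResult:
    k: int
    bic_by_k: pd.Series
    n_pcs_retained: int
    scores: pd.DataFrame
    assignments: pd.Series


@dataclass
class AdmixtureRun:
    K: int
    seed: int
    loglik: float
    Q: pd.DataFrame
    theta: np.ndarray


@dataclass
class EvannoTable:
    table: pd.DataFrame
    best_k: int


def hamming_distances(m: MarkerMatrix, normalized: bool = False) -> DistanceMatrix:
    """Pairwise Hamming dissimilarity between individuals (count of loci
    with differing band state; divide by L if ``normalized``)."""
    m.require_complete()
    d = squareform(pdist(m.bands.astype(float), metric="hamming")) * m.n_loci
    if normalized:
        d = d / m.n_loci
    return DistanceMatrix(list(m.individual_ids), d, metric="hamming")


def minimum_spanning_network(
    d: DistanceMatrix, pop_of: dict | None = None
) -> NetworkResult:
    """Minimum spanning tree with tied alternative edges retained.

    A minimum spanning tree is built by Kruskal with a deterministic
    (weight, label, label) edge order; afterwards every non-tree edge whose
    weight equals the bottleneck (maximum edge weight) on the tree path
    between its endpoints is added, yielding the usual population-genetics
    network that keeps equally short alternatives.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    edges = sorted(
        ((float(d.values[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = nx.Graph()
    tree.add_nodes_from(range(n))
    mst_edges = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.add_edge(i, j, weight=w)
            mst_edges.append((i, j, w))

    extra = []
    for w, i, j in edges:
        if tree.has_edge(i, j):
            continue
        path = nx.shortest_path(tree, i, j)
        bottleneck = max(
            tree[a][b]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        if np.isclose(w, bottleneck):
            extra.append((i, j, w))

    lab = d.labels
    nodes = [(x, pop_of.get(x) if pop_of else None) for x in lab]
    out_edges = [(lab[i], lab[j], w) for i, j, w in mst_edges + extra]
    return NetworkResult(nodes=nodes, edges=out_edges, is_spanning=True)


def pca(m: MarkerMatrix) -> OrdinationResult:
    """Covariance-matrix PCA of the band table (column-centred, unscaled).

    Component signs follow the convention that the largest-magnitude
    loading of each component is positive, making output deterministic.
    """
    m.require_complete()
    X = m.bands.astype(float)
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    # sign convention
    for c in range(Vt.shape[0]):
        jmax = np.argmax(np.abs(Vt[c]))
        if Vt[c, jmax] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * s
    comp = [f"PC{c + 1}" for c in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=m.individual_ids, columns=comp),
        eigenvalues=eig,
        pct_variance=pct,
        loadings=pd.DataFrame(Vt.T, index=m.locus_ids, columns=comp),
    )


def dapc(
    m: MarkerMatrix,
    k: int | None = None,
    n_pcs: int | None = None,
    seed: int = 0,
    k_max: int | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components.

    Groups are found by seeded k-means (25 restarts) on retained PC scores
    over k = 1..k_max, choosing k by BIC = n ln(WSS/n) + k ln(n), unless
    ``k`` is given.  Retained PCs default to the smallest count explaining
    >= 80% of variance.  Linear discriminant analysis of the retained PCs
    against the groups yields at most k - 1 discriminant functions.
    """
    n = m.n_individuals
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds {n} individuals")
    ord_res = pca(m)
    pos = ord_res.eigenvalues > 1e-12
    if n_pcs is None:
        cum = np.cumsum(ord_res.pct_variance)
        n_pcs = int(np.searchsorted(cum, 80.0) + 1)
    n_pcs = int(min(n_pcs, pos.sum(), n - 1)) or 1
    Z = ord_res.scores.to_numpy()[:, :n_pcs]
    # group discovery uses the full PC space (standard find-clusters
    # practice: dimension reduction is for the discriminant step only)
    Zfull = ord_res.scores.to_numpy()[:, : max(int(pos.sum()), 1)]

    if k_max is None:
        k_max = min(10, n - 1)
    bics = {}
    labels_by_k = {}
    total_ss = float(((Zfull - Zfull.mean(axis=0)) ** 2).sum())
    for kk in range(1, k_max + 1):
        if kk == 1:
            wss = total_ss
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=kk, n_init=25, random_state=seed).fit(Zfull)
            wss = float(km.inertia_)
            labels_by_k[kk] = km.labels_
        wss = max(wss, 1e-12)
        bics[kk] = n * np.log(wss / n) + kk * np.log(n)
    bic_by_k = pd.Series(bics)
    chosen_k = int(k) if k is not None else int(bic_by_k.idxmin())
    if chosen_k not in labels_by_k:
        km = KMeans(n_clusters=chosen_k, n_init=25, random_state=seed).fit(Zfull)
        labels_by_k[chosen_k] = km.labels_
    groups = labels_by_k[chosen_k]

    if chosen_k == 1:
        scores = pd.DataFrame(index=m.individual_ids)
    else:
        lda = LinearDiscriminantAnalysis(n_components=min(chosen_k - 1, n_pcs))
        ld = lda.fit_transform(Z, groups)
        scores = pd.DataFrame(
            ld,
            index=m.individual_ids,
            columns=[f"LD{c + 1}" for c in range(ld.shape[1])],
        )
    return DapcResult(
        k=chosen_k,
        bic_by_k=bic_by_k,
        n_pcs_retained=n_pcs,
        scores=scores,
        assignments=pd.Series(groups, index=m.individual_ids),
    )


def admixture_mcmc(
    m: MarkerMatrix,
    K: int,
    n_burnin: int = 2000,
    n_sample: int = 5000,
    seed: int = 0,
    thin: int = 10,
) -> AdmixtureRun:
    """Gibbs-sampled Bayesian admixture for binary band phenotypes.

    Returns the posterior-mean admixture matrix Q (label switching
    resolved by optimally matching cluster band-frequency vectors across
    retained draws) and L(K), the posterior mean of the marginal data
    log-likelihood over post-burn-in draws.
    """
    m.require_complete()
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m.n_individuals:
        raise ValueError(f"K={K} exceeds {m.n_individuals} individuals")
    if min(n_burnin, n_sample) < 1:
        raise ValueError("iteration counts must be >= 1")
    x = np.ascontiguousarray(m.bands, dtype=np.int8)
    theta_s, q_s, ll_s = gibbs_admixture(
        x, K, int(n_burnin), int(n_sample), int(thin), int(seed) % (2**31)
    )
    # align cluster labels across draws against the first retained draw
    ref = theta_s[0]
    q_sum = np.zeros_like(q_s[0])
    theta_sum = np.zeros_like(ref)
    for t in range(theta_s.shape[0]):
        cost = ((theta_s[t][:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[cols] = rows
        q_sum += q_s[t][:, perm]
        theta_sum += theta_s[t][perm]
    S = theta_s.shape[0]
    Q = pd.DataFrame(
        q_sum / S,
        index=m.individual_ids,
        columns=[f"cluster{k + 1}" for k in range(K)],
    )
    return AdmixtureRun(
        K=K, seed=seed, loglik=float(ll_s.mean()), Q=Q, theta=theta_sum / S
    )


def evanno(runs: list) -> EvannoTable:
    """Evanno ΔK over replicate admixture runs grouped by K.

    ΔK = |L''(K)| / sd(L(K)) is defined for interior K only; the best K is
    the interior K with maximal ΔK.  A zero replicate standard deviation
    yields an infinite ΔK (with a warning).
    """
    by_k: dict = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.loglik)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    short = [k for k in ks if len(by_k[k]) < 2]
    if short:
        raise ValueError(f"need >= 2 replicates per K; short at K={short}")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    lp = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    rows = []
    for k in ks:
        lpp = abs(lp[k + 1] - lp[k]) if (k in lp and k + 1 in lp) else np.nan
        if not np.isnan(lpp):
            if sd[k] == 0:
                warnings.warn(f"sd(L(K)) = 0 at K={k}; ΔK reported as inf")
                dk = np.inf
            else:
                dk = lpp / sd[k]
        else:
            dk = np.nan
        rows.append(
            {
                "K": k,
                "mean_L": mean[k],
                "sd_L": sd[k],
                "Lprime": lp.get(k, np.nan),
                "Lpp_abs": lpp,
                "deltaK": dk,
            }
        )
    table = pd.DataFrame(rows).set_index("K")
    interior = table["deltaK"].dropna()
    best = int(interior.idxmax())
    return EvannoTable(table=table, best_k=best)
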