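"""Among-population differentiation, gene flow and isolation by distance.

Implements Nei's Gst on Lynch–Milligan allele frequencies, a one-level
AMOVA on squared Euclidean (= Hamming) distances between band vectors with
a permutation test, the Crow–Aoki island-model gene-flow estimate with the
finite-deme correction alpha = (n/(n-1))**2, pairwise Phi_st with Slatkin
linearization Fst/(1-Fst), and a Mantel test of log geographic distance
against linearized differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .diversity import LocusFrequencies, estimate_freqs
from .marker_data import MarkerMatrix, PopulationGeo

__all__ = [
    "AmovaResult",
    "DifferentiationResult",
    "MantelResult",
    "nei_gst",
    "amova_binary",
    "gene_flow_crow_aoki",
    "pairwise_fst",
    "mantel_ibd",
]


@dataclass
class AmovaResult:
    """One-level AMOVA: variance components, Phi_st and permutation p."""

    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    n_permutations: int
    p_value: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "sigma2": [self.sigma2_among, self.sigma2_within],
                "pct": [self.pct_among, self.pct_within],
            },
            index=["among", "within"],
        )


@dataclass
class DifferentiationResult:
    """Gst partition, gene flow and pairwise differentiation matrices."""

    gst: float
    ht: float
    hs: float
    nm: float | None = None
    alpha: float | None = None
    n_pops: int | None = None
    pairwise_fst: pd.DataFrame | None = None
    linearized: pd.DataFrame | None = None


@dataclass
class MantelResult:
    """Matrix correlation between genetic and geographic distance."""

    r: float
    p: float
    n_permutations: int
    spearman_rho: float
    ci95: tuple = (np.nan, np.nan)


def nei_gst(f: LocusFrequencies) -> DifferentiationResult:
    """Nei's gene-diversity partition Gst = (Ht - Hs) / Ht.

    Per locus, Hs is the mean within-population gene diversity 2pq and Ht
    the diversity 2*p_bar*q_bar at the across-population mean frequency.
    Loci with Ht = 0 carry no diversity and are excluded; Gst is the
    ratio of summed components over the remaining loci.
    """
    if len(f.populations) < 2:
        raise ValueError("Gst needs >= 2 populations")
    p = f.p.to_numpy()
    q = f.q.to_numpy()
    hs = (2.0 * p * q).mean(axis=0)
    p_bar = p.mean(axis=0)
    ht = 2.0 * p_bar * (1.0 - p_bar)
    keep = ht > 0
    if not keep.any():
        raise ValueError("all loci monomorphic everywhere; Gst undefined")
    ht_sum = ht[keep].sum()
    hs_sum = hs[keep].sum()
    return DifferentiationResult(
        gst=float((ht_sum - hs_sum) / ht_sum),
        ht=float(ht[keep].mean()),
        hs=float(hs[keep].mean()),
        n_pops=len(f.populations),
    )


def _amova_ss(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray):
    """Sums of squares from a squared-distance matrix (Excoffier)."""
    N = d2.shape[0]
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for g in labels:
        ix = np.flatnonzero(groups == g)
        sub = d2[np.ix_(ix, ix)]
        ss_within += sub[np.triu_indices(len(ix), 1)].sum() / len(ix)
    return ss_total, ss_within


def amova_binary(
    m: MarkerMatrix, n_perm: int = 10000, seed: int = 0
) -> AmovaResult:
    """AMOVA for binary band data with a permutation test on Phi_st.

    Distances are squared Euclidean on the 0/1 band vectors (identical to
    Hamming counts).  Variance components use the standard estimator with
    the weighted average sample size n0; significance permutes individuals
    among populations keeping population sizes fixed, with the add-one
    p-value convention (1 + #{Phi_perm >= Phi_obs}) / (1 + n_perm).
    """
    m.require_complete()
    pops = m.populations
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    sizes = m.pop_sizes()
    bad = [p for p, n in sizes.items() if n < 2]
    if bad:
        raise ValueError(
            f"populations with a single individual (within-group df = 0): {bad}"
        )
    X = m.bands.astype(float)
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    groups = m.pop_labels
    labels = np.array(pops)
    N = X.shape[0]
    g = len(pops)
    n_g = np.array([sizes[p] for p in pops], dtype=float)
    n0 = (N - (n_g**2).sum() / N) / (g - 1)

    def phi_from(groups_arr):
        ss_total, ss_within = _amova_ss(d2, groups_arr, labels)
        ss_among = ss_total - ss_within
        msa = ss_among / (g - 1)
        msw = ss_within / (N - g)
        s2w = msw
        s2a = (msa - msw) / n0
        denom = s2a + s2w
        phi = s2a / denom if denom > 0 else 0.0
        return ss_among, ss_within, s2a, s2w, phi

    ss_among, ss_within, s2a, s2w, phi = phi_from(groups)
    total = s2a + s2w
    pct_among = 100.0 * s2a / total if total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        hits += phi_from(perm)[4] >= phi - 1e-12
    p = (1.0 + hits) / (1.0 + n_perm) if n_perm > 0 else np.nan

    return AmovaResult(
        sigma2_among=float(s2a),
        sigma2_within=float(s2w),
        pct_among=float(pct_among),
        pct_within=float(100.0 - pct_among),
        phi_st=float(phi),
        df_among=g - 1,
        df_within=N - g,
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        n_permutations=n_perm,
        p_value=float(p),
    )


def gene_flow_crow_aoki(gst: float, n_pops: int) -> float:
    """Migrants per generation Nm = ((1/Gst) - 1) / (4 alpha).

    ``alpha = (n/(n-1))**2`` corrects the island-model formula for a finite
    number of demes n.
    """
    if n_pops < 2:
        raise ValueError("need >= 2 populations")
    if not (0.0 < gst <= 1.0):
        raise ValueError(
            "Gst must lie in (0, 1]; Gst = 0 implies unbounded gene flow"
        )
    alpha = (n_pops / (n_pops - 1.0)) ** 2
    return ((1.0 / gst) - 1.0) / (4.0 * alpha)


def pairwise_fst(m: MarkerMatrix) -> DifferentiationResult:
    """Pairwise Phi_st (two-population AMOVA per pair) and its Slatkin
    linearization Fst/(1-Fst); Fst = 1 maps to +inf with a warning."""
    pops = m.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    k = len(pops)
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    lin = pd.DataFrame(0.0, index=pops, columns=pops)
    for a in range(k):
        for b in range(a + 1, k):
            sub = m.subset(keep_populations=[pops[a], pops[b]])
            res = amova_binary(sub, n_perm=0)
            f = max(res.phi_st, 0.0)
            fst.iloc[a, b] = fst.iloc[b, a] = f
            if f >= 1.0:
                warnings.warn(
                    f"Fst = 1 between {pops[a]!r} and {pops[b]!r}; "
                    "linearized value is infinite"
                )
                val = np.inf
            else:
                val = f / (1.0 - f)
            lin.iloc[a, b] = lin.iloc[b, a] = val
    gst_res = nei_gst(estimate_freqs(m))
    nm = gene_flow_crow_aoki(gst_res.gst, k) if gst_res.gst > 0 else np.inf
    return DifferentiationResult(
        gst=gst_res.gst,
        ht=gst_res.ht,
        hs=gst_res.hs,
        nm=nm,
        alpha=(k / (k - 1.0)) ** 2,
        n_pops=k,
        pairwise_fst=fst,
        linearized=lin,
    )


def _upper(v: np.ndarray) -> np.ndarray:
    return v[np.triu_indices(v.shape[0], 1)]


def mantel_ibd(
    gen: pd.DataFrame,
    geo: PopulationGeo,
    n_perm: int = 10000,
    seed: int = 0,
    n_boot: int = 1000,
) -> MantelResult:
    """Mantel test: log10 geographic distance vs linearized differentiation.

    The permutation null shuffles population labels of the genetic matrix
    (rows and columns jointly); the test is one-sided against positive
    isolation by distance (r_perm >= r_obs).  A bootstrap over population
    pairs gives a 95% percentile interval for r.
    """
    pops = list(gen.index)
    if len(pops) < 4:
        raise ValueError("need >= 4 populations for a meaningful Mantel null")
    geo_d = geo.distance_matrix(order=pops).to_numpy()
    if (_upper(geo_d) <= 0).any():
        raise ValueError("zero geographic distance between distinct populations")
    gvec = _upper(gen.to_numpy())
    dvec = np.log10(_upper(geo_d))
    r_obs = float(np.corrcoef(dvec, gvec)[0, 1])
    rho = float(stats.spearmanr(dvec, gvec)[0])

    G = gen.to_numpy()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pops))
        r = np.corrcoef(dvec, _upper(G[np.ix_(perm, perm)]))[0, 1]
        hits += r >= r_obs - 1e-12
    p = (1.0 + hits) / (1.0 + n_perm)

    ci = (np.nan, np.nan)
    if n_boot:
        idx = np.arange(len(gvec))
        rs = []
        for _ in range(n_boot):
            b = rng.choice(idx, size=len(idx), replace=True)
            if np.std(dvec[b]) > 0 and np.std(gvec[b]) > 0:
                rs.append(np.corrcoef(dvec[b], gvec[b])[0, 1])
        if rs:
            ci = tuple(np.percentile(rs, [2.5, 97.5]))

    return MantelResult(
        r=r_obs, p=float(p), n_permutations=n_perm, spearman_rho=rho, ci95=ci
    )
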