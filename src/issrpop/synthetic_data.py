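"""Synthetic dominant-marker datasets with controlled population structure.

The generator emulates the sampling design of a small conservation-genetics
survey: a handful of populations descended from a few ancestral clusters,
genotyped at independent biallelic dominant loci.  Population allele
frequencies are drawn around each cluster's ancestral frequency with the
Balding–Nichols Beta model, whose concentration is governed by an
Fst-like differentiation parameter, so the degree of among-population
structure is a designed-in truth that downstream estimators can be checked
against.  Diploid genotypes are drawn under Hardy–Weinberg and collapsed to
band phenotypes by dominant masking: the band shows iff at least one
dominant allele is present, so the expected band frequency at a locus is
``1 - (1 - p)**2``.

Population-exclusive ("private") bands can be injected at chosen
populations; they are observed nowhere else by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .marker_data import MarkerMatrix, PopulationGeo

__all__ = ["SimDesign", "generate", "study_preset", "STUDY_POPULATIONS"]

#: The six study populations (cliff sites in central Mexico).
STUDY_POPULATIONS = (
    "Presa Cebolletas",
    "Mesa Montoro",
    "Presa Malpaso",
    "Rio Gil",
    "Puente Cuates",
    "Barranca Tortugas",
)

#: Two ancestral clusters: one containing the four hydrologically connected
#: sites, the other the two most isolated ones.
STUDY_CLUSTERS = {
    "Presa Malpaso": 0,
    "Puente Cuates": 0,
    "Rio Gil": 0,
    "Mesa Montoro": 0,
    "Barranca Tortugas": 1,
    "Presa Cebolletas": 1,
}


@dataclass
class SimDesign:
    """Parameters of a synthetic dominant-marker dataset.

    ``fst_target`` is the Balding–Nichols differentiation parameter for
    population frequencies around their ancestral cluster frequency;
    ``private_allele_spec`` maps populations to the number of injected
    population-exclusive band loci (appended after the ``n_loci`` base
    loci).  ``clone_rate`` duplicates genotypes within a population to
    emulate clonal reproduction; the default 0 reflects field sampling
    spaced to exclude clones.
    """

    n_pops: int = 6
    n_per_pop: int = 20
    n_loci: int = 60
    k_ancestral: int = 2
    pop_to_cluster: dict = field(default_factory=dict)
    fst_target: float = 0.45
    private_allele_spec: dict = field(default_factory=dict)
    pop_names: tuple = ()
    geo: PopulationGeo | None = None
    clone_rate: float = 0.0
    cluster_share: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.pop_names:
            self.pop_names = tuple(f"pop{i + 1}" for i in range(self.n_pops))
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")
        if not self.pop_to_cluster:
            self.pop_to_cluster = {
                p: i % self.k_ancestral for i, p in enumerate(self.pop_names)
            }
        missing = set(self.pop_names) - set(self.pop_to_cluster)
        if missing:
            raise ValueError(f"pop_to_cluster misses populations: {sorted(missing)}")
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError("fst_target must lie in (0, 1)")
        if min(self.n_pops, self.n_per_pop, self.n_loci) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.clone_rate < 1.0):
            raise ValueError("clone_rate must lie in [0, 1)")
        if not (0.0 <= self.cluster_share < 1.0):
            raise ValueError("cluster_share must lie in [0, 1)")


def _balding_nichols(rng, p0: float, fst: float) -> float:
    a = p0 * (1.0 - fst) / fst
    b = (1.0 - p0) * (1.0 - fst) / fst
    return float(rng.beta(a, b))


def generate(design: SimDesign, seed: int | None = None):
    """Draw a marker matrix from ``design``.

    Returns ``(MarkerMatrix, truth)`` where ``truth`` records the simulated
    per-population allele frequencies, cluster assignments, the
    differentiation parameter, and the injected private loci.  The same
    seed yields bit-identical output.

    ``seed`` overrides ``design.seed`` when given.
    """
    if design.n_loci < 1:
        raise ValueError("degenerate design: 0 loci")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    pops = list(design.pop_names)
    n_private = sum(design.private_allele_spec.get(p, 0) for p in pops)
    L = design.n_loci + n_private

    # Hierarchical Balding-Nichols: a shared ancestral frequency per locus,
    # cluster frequencies diverged around it, population frequencies diverged
    # around their cluster.  The two levels compose so the total
    # differentiation parameter among populations equals fst_target:
    # F_tot = f_c + f_p (1 - f_c) with the cluster level carrying
    # cluster_share of the total.  Frequencies are clipped away from
    # fixation so base simulation loci stay informative.
    f_c = design.cluster_share * design.fst_target
    f_p = (design.fst_target - f_c) / (1.0 - f_c)
    p0 = rng.uniform(0.05, 0.95, size=design.n_loci)
    p_cluster = np.zeros((design.k_ancestral, design.n_loci))
    for c in range(design.k_ancestral):
        for l in range(design.n_loci):
            p_cluster[c, l] = (
                _balding_nichols(rng, p0[l], f_c) if f_c > 0 else p0[l]
            )
    p_cluster = np.clip(p_cluster, 0.01, 0.99)
    p_pop = np.zeros((design.n_pops, design.n_loci))
    for i, pop in enumerate(pops):
        c = design.pop_to_cluster[pop]
        for l in range(design.n_loci):
            p_pop[i, l] = _balding_nichols(rng, p_cluster[c, l], f_p)
    p_pop = np.clip(p_pop, 0.01, 0.99)

    n = design.n_per_pop
    bands = np.zeros((design.n_pops * n, L), dtype=np.int8)
    ids, pop_of = [], {}
    for i, pop in enumerate(pops):
        # two Bernoulli(p) allele draws per individual/locus; dominant
        # masking: band present iff >= 1 dominant allele
        g = rng.random((n, design.n_loci, 2)) < p_pop[i][None, :, None]
        geno = g.sum(axis=2)
        if design.clone_rate > 0 and n > 1:
            for j in range(1, n):
                if rng.random() < design.clone_rate:
                    geno[j] = geno[rng.integers(0, j)]
        bands[i * n : (i + 1) * n, : design.n_loci] = (geno > 0).astype(np.int8)
        for j in range(n):
            label = f"{pop.replace(' ', '_')}_{j + 1:02d}"
            ids.append(label)
            pop_of[label] = pop

    # private loci: band phenotype frequency ~0.3 in the target population,
    # structurally absent everywhere else
    private_loci = {}
    col = design.n_loci
    for pop in pops:
        for k in range(design.private_allele_spec.get(pop, 0)):
            i = pops.index(pop)
            carriers = rng.random(n) < 0.3
            if not carriers.any():
                carriers[rng.integers(0, n)] = True
            bands[i * n : (i + 1) * n, col] = carriers.astype(np.int8)
            locus_id = f"priv_{pop.replace(' ', '_')}_{k + 1}"
            private_loci[locus_id] = pop
            col += 1

    locus_ids = [f"L{l + 1:03d}" for l in range(design.n_loci)] + list(private_loci)
    m = MarkerMatrix(ids, locus_ids, bands, pop_of)
    truth = {
        "p_pop": p_pop,
        "populations": pops,
        "clusters": dict(design.pop_to_cluster),
        "fst_target": design.fst_target,
        "private_loci": private_loci,
    }
    return m, truth


def _study_geo() -> PopulationGeo:
    """Illustrative site layout scaled so the mean pairwise distance is
    5.99 km (the surveyed sites' stated average separation)."""
    base = {
        "Presa Cebolletas": (0.0, 0.0),
        "Mesa Montoro": (2.1, 3.4),
        "Presa Malpaso": (4.9, 1.2),
        "Rio Gil": (5.8, 4.1),
        "Puente Cuates": (7.6, 2.2),
        "Barranca Tortugas": (1.4, 6.3),
    }
    xy = np.array(list(base.values()))
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    mean = d[np.triu_indices(len(base), 1)].mean()
    scale = 5.99 / mean
    return PopulationGeo({p: (x * scale, y * scale) for p, (x, y) in base.items()})


def study_preset(seed: int = 2022) -> SimDesign:
    """Default design matching the survey: 6 populations x 20 individuals,
    two ancestral clusters (4 + 2 populations), differentiation 0.45,
    60 base loci plus 5 private bands (4 at Presa Cebolletas, 1 at Puente
    Cuates), mean inter-site distance ~6 km."""
    return SimDesign(
        n_pops=6,
        n_per_pop=20,
        n_loci=60,
        k_ancestral=2,
        pop_to_cluster=dict(STUDY_CLUSTERS),
        fst_target=0.45,
        private_allele_spec={"Presa Cebolletas": 4, "Puente Cuates": 1},
        pop_names=STUDY_POPULATIONS,
        geo=_study_geo(),
        seed=seed,
    )
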