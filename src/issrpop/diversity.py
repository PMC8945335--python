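"""Per-population diversity statistics for dominant binary markers.

Dominant markers hide heterozygotes, so allele frequencies must be
recovered from the band-absence fraction ``x`` (the frequency of the
recessive homozygote under Hardy–Weinberg).  The naive estimate
``q = sqrt(x)`` is biased at small sample sizes; the Lynch–Milligan
Taylor-expansion correction

    q_hat = sqrt(x) * [1 - Var(x_hat) / (8 x**2)]**(-1),   Var(x_hat) = x(1-x)/n

is used throughout, clamped into [0, 1], with ``x = 0`` short-circuited to
``q = 0``.  Expected heterozygosity He = 2pq, Shannon information
I = -(p ln p + q ln q) and the 95%-criterion polymorphism rate are then
computed from the estimated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .marker_data import MarkerMatrix

__all__ = [
    "LocusFrequencies",
    "DiversitySummary",
    "estimate_freqs",
    "allele_counts",
    "heterozygosity",
    "diversity_summary",
    "exact_differentiation_test",
]


@dataclass
class LocusFrequencies:
    """Per-population, per-locus frequency estimates.

    All fields are populations x loci frames: ``x`` the band-absence
    fraction, ``q`` the estimated recessive (null) allele frequency,
    ``p = 1 - q`` the dominant allele frequency, and ``band_freq`` the raw
    phenotypic band frequency.  ``n`` gives individuals sampled per
    population.
    """

    x: pd.DataFrame
    q: pd.DataFrame
    p: pd.DataFrame
    band_freq: pd.DataFrame
    n: pd.Series

    @property
    def populations(self) -> list:
        return list(self.x.index)


@dataclass
class DiversitySummary:
    """Per-population diversity table plus across-population mean and SE.

    ``table`` columns: ``Na`` (observed locus states summed over loci),
    ``Ne`` (effective number of alleles), ``private`` (population-exclusive
    bands), ``He``, ``I``, ``pctP``.
    """

    table: pd.DataFrame
    mean: pd.Series
    se: pd.Series


def estimate_freqs(m: MarkerMatrix) -> LocusFrequencies:
    """Lynch–Milligan allele-frequency estimates per population and locus."""
    m.require_complete()
    sizes = m.pop_sizes()
    for pop, n in sizes.items():
        if n < 2:
            raise ValueError(
                f"population {pop!r} has n={n}; the bias correction needs n >= 2"
            )
    counts = m.pop_band_counts()
    n = pd.Series(sizes)[counts.index]
    band_freq = counts.div(n, axis=0)
    x = 1.0 - band_freq

    xv = x.to_numpy(dtype=float)
    nv = n.to_numpy(dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        var = xv * (1.0 - xv) / nv
        corr = 1.0 - var / (8.0 * xv**2)
        q = np.sqrt(xv) / corr
    q = np.where(xv == 0.0, 0.0, q)
    q = np.clip(q, 0.0, 1.0)

    qf = pd.DataFrame(q, index=x.index, columns=x.columns)
    return LocusFrequencies(x=x, q=qf, p=1.0 - qf, band_freq=band_freq, n=n)


def allele_counts(m: MarkerMatrix, freqs: LocusFrequencies | None = None) -> pd.DataFrame:
    """Observed (Na), effective (Ne) and private allele counts per population.

    Na counts observed band states per locus (2 if the population is
    polymorphic at the locus, 1 if monomorphic) summed over loci.  A private
    band is a locus whose band occurs in exactly this population.  Ne is the
    mean over loci of ``1 / (p**2 + q**2)`` on the estimated frequencies.
    """
    if freqs is None:
        freqs = estimate_freqs(m)
    counts = m.pop_band_counts()
    n = freqs.n
    present = counts.gt(0)
    # polymorphic within a population: both states seen
    poly = counts.gt(0) & counts.lt(n, axis=0)
    na = (poly.astype(int) + 1).sum(axis=1)
    only_here = present & (present.sum(axis=0) == 1)
    private = only_here.sum(axis=1)
    p, q = freqs.p.to_numpy(), freqs.q.to_numpy()
    ne = pd.Series((1.0 / (p**2 + q**2)).mean(axis=1), index=counts.index)
    return pd.DataFrame({"Na": na, "Ne": ne, "private": private})


def heterozygosity(freqs: LocusFrequencies, on_band_freqs: bool = False) -> pd.DataFrame:
    """He, Shannon I and %P (95% criterion) per population.

    He and I are computed on estimated allele frequencies by default; pass
    ``on_band_freqs=True`` to use raw phenotype frequencies instead (the
    convention differs between dominant-data programs).  A locus counts as
    polymorphic when its commonest band state does not exceed frequency
    0.95.
    """
    if on_band_freqs:
        p = freqs.band_freq.to_numpy()
        q = 1.0 - p
    else:
        p = freqs.p.to_numpy()
        q = freqs.q.to_numpy()
    he = (2.0 * p * q).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon_terms = -(
            np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0)
        )
    shannon = shannon_terms.mean(axis=1)
    bf = freqs.band_freq.to_numpy()
    major = np.maximum(bf, 1.0 - bf)
    pctp = 100.0 * (major <= 0.95).mean(axis=1)
    return pd.DataFrame(
        {"He": he, "I": shannon, "pctP": pctp}, index=freqs.x.index
    )


def diversity_summary(m: MarkerMatrix, on_band_freqs: bool = False) -> DiversitySummary:
    """Full per-population diversity table with across-population mean +- SE.

    The dispersion column is the standard error sd / sqrt(n_pops), matching
    the usual "mean +- SE" reporting style of survey tables.
    """
    freqs = estimate_freqs(m)
    table = allele_counts(m, freqs).join(heterozygosity(freqs, on_band_freqs))
    mean = table.mean()
    se = table.std(ddof=1) / np.sqrt(len(table)) if len(table) > 1 else table.std()
    return DiversitySummary(table=table, mean=mean, se=se)


def exact_differentiation_test(
    m: MarkerMatrix, n_tables: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Exact test of allele-frequency homogeneity among populations.

    Per locus, tests the populations x {band, no band} contingency table:
    Fisher's exact test by full hypergeometric enumeration for two
    populations, and a Monte-Carlo exact test (>= ``n_tables`` sampled
    tables with fixed margins, seeded) otherwise.  Returns one row per
    locus plus a ``combined`` row with the Fisher's-method combination
    across loci.
    """
    m.require_complete()
    pops = m.populations
    if len(pops) < 2:
        raise ValueError("the exact differentiation test needs >= 2 populations")
    counts = m.pop_band_counts()
    sizes = pd.Series(m.pop_sizes())[counts.index]
    rng = np.random.default_rng(seed)
    pvals = {}
    for locus in m.locus_ids:
        band = counts[locus].to_numpy()
        table = np.column_stack([band, sizes.to_numpy() - band])
        if table.sum(axis=0).min() == 0:
            pvals[locus] = 1.0  # monomorphic overall: single attainable table
        elif len(pops) == 2:
            pvals[locus] = float(stats.fisher_exact(table)[1])
        else:
            pvals[locus] = _monte_carlo_exact(table, n_tables, rng)
    out = pd.DataFrame({"p": pvals})
    _, comb = stats.combine_pvalues(out["p"].to_numpy(), method="fisher")
    out.loc["combined"] = comb
    return out


def _monte_carlo_exact(table: np.ndarray, n_tables: int, rng) -> float:
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    dist = stats.random_table(rows, cols)
    logp_obs = dist.logpmf(table)
    sampled = dist.rvs(n_tables, random_state=rng)
    logp = dist.logpmf(sampled)
    # add-one rule keeps the Monte-Carlo p away from 0
    return float((1 + (logp <= logp_obs + 1e-9).sum()) / (1 + n_tables))
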