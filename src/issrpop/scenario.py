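"""Genetic-erosion scenarios: decline and local-extinction simulations.

A scenario perturbs the marker matrix — removing a random fraction of
individuals from every population (decline) or dropping whole populations
(local extinction) — and the full metric suite is recomputed on the
perturbed matrix with identical settings, so baseline and scenario results
are directly comparable.  The shift in per-population private-allele
counts is summarised by a goodness-of-fit chi-square of the post-scenario
counts against the baseline counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differentiation import AmovaResult, amova_binary, nei_gst, gene_flow_crow_aoki
from .diversity import DiversitySummary, allele_counts, diversity_summary, estimate_freqs
from .marker_data import MarkerMatrix

__all__ = ["ScenarioSpec", "ScenarioComparison", "apply_scenario", "compare_scenarios"]


@dataclass
class ScenarioSpec:
    """A perturbation of the sampled individuals.

    ``kind`` is one of ``decline`` (remove ``fraction_removed`` of each
    population, i.e. floor(fraction * n) individuals drawn uniformly
    without replacement), ``extinction`` (drop ``removed_populations``
    entirely) or ``none`` (identity).
    """

    kind: str = "none"
    fraction_removed: float = 0.5
    removed_populations: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("decline", "extinction", "none"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "decline" and not (0.0 < self.fraction_removed < 1.0):
            raise ValueError("fraction_removed must lie in (0, 1)")


@dataclass
class ScenarioComparison:
    baseline_diversity: DiversitySummary
    perturbed_diversity: DiversitySummary
    baseline_gst: float
    perturbed_gst: float
    baseline_nm: float
    perturbed_nm: float
    baseline_amova: AmovaResult
    perturbed_amova: AmovaResult
    private_before: pd.Series
    private_after: pd.Series
    chi2: float
    chi2_df: int
    chi2_p: float


def apply_scenario(m: MarkerMatrix, s: ScenarioSpec) -> MarkerMatrix:
    """Return the perturbed matrix (deterministic under ``s.seed``)."""
    if s.kind == "none":
        return m
    if s.kind == "extinction":
        keep = [p for p in m.populations if p not in set(s.removed_populations)]
        unknown = set(s.removed_populations) - set(m.populations)
        if unknown:
            raise KeyError(f"unknown populations: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("extinction must leave >= 2 populations")
        return m.subset(keep_populations=keep)
    rng = np.random.default_rng(s.seed)
    labels = m.pop_labels
    keep_ids = []
    for pop in m.populations:
        ids = [i for i, l in zip(m.individual_ids, labels) if l == pop]
        n_remove = int(np.floor(s.fraction_removed * len(ids)))
        if n_remove >= len(ids):
            raise ValueError(f"removal would empty population {pop!r}")
        removed = set(rng.choice(len(ids), size=n_remove, replace=False).tolist())
        keep_ids.extend(i for k, i in enumerate(ids) if k not in removed)
    return m.subset(keep_individuals=keep_ids)


def private_allele_chi2(before: pd.Series, after: pd.Series):
    """Goodness-of-fit chi-square of post-scenario private-allele counts
    against baseline counts.

    chi2 = sum (after - before)**2 / before over per-population cells;
    populations with a baseline count of zero are pooled into one cell,
    and the pooled cell is dropped if its baseline is still zero (its
    contribution is undefined).  df = #cells - 1, p from the chi-square
    upper tail.  Populations absent after the scenario contribute an
    observed count of 0.
    """
    after = after.reindex(before.index, fill_value=0)
    nz = before[before > 0]
    obs = after[nz.index].to_numpy(dtype=float)
    exp = nz.to_numpy(dtype=float)
    zero_pool_exp = float(before[before == 0].sum())
    zero_pool_obs = float(after[before[before == 0].index].sum())
    cells_obs = list(obs)
    cells_exp = list(exp)
    if zero_pool_exp > 0:
        cells_obs.append(zero_pool_obs)
        cells_exp.append(zero_pool_exp)
    if not cells_exp:
        return 0.0, 0, 1.0
    chi2 = float(
        sum((o - e) ** 2 / e for o, e in zip(cells_obs, cells_exp))
    )
    df = max(len(cells_exp) - 1, 1)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def compare_scenarios(
    m: MarkerMatrix,
    s: ScenarioSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScenarioComparison:
    """Run the diversity and differentiation suite on the baseline and the
    perturbed matrix with identical settings and compare."""
    perturbed = apply_scenario(m, s)

    def suite(mat):
        div = diversity_summary(mat)
        gst = nei_gst(estimate_freqs(mat))
        nm = gene_flow_crow_aoki(gst.gst, len(mat.populations)) if gst.gst > 0 else np.inf
        am = amova_binary(mat, n_perm=n_perm, seed=seed)
        priv = allele_counts(mat)["private"]
        return div, gst.gst, nm, am, priv

    b_div, b_gst, b_nm, b_am, b_priv = suite(m)
    p_div, p_gst, p_nm, p_am, p_priv = suite(perturbed)
    chi2, df, p = private_allele_chi2(b_priv, p_priv)
    return ScenarioComparison(
        baseline_diversity=b_div,
        perturbed_diversity=p_div,
        baseline_gst=b_gst,
        perturbed_gst=p_gst,
        baseline_nm=b_nm,
        perturbed_nm=p_nm,
        baseline_amova=b_am,
        perturbed_amova=p_am,
        private_before=b_priv,
        private_after=p_priv,
        chi2=chi2,
        chi2_df=df,
        chi2_p=p,
    )
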