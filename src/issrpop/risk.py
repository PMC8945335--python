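"""Conservation-status rule engines: MER scoring and a simplified IUCN mapper.

The MER (the extinction-risk evaluation method of Mexico's NOM-059
standard, Appendix II) scores four criteria — (A) breadth of distribution,
(B) habitat status, (C) intrinsic biological vulnerability (ecological and
genetic), (D) human impact — each qualitative level mapped to a number in
ascending order of risk, normalized by the criterion maximum and summed.
Category thresholds on the total: >= 2.0 in danger of extinction (EE),
[1.70, 2.0) threatened (E), [1.5, 1.70) special protection (Pr).  The
boundary 1.70 is assigned to the higher-risk category E (precautionary
reading of the overlapping published intervals).

Genetic evidence enters criterion C as a sub-score; C takes the maximum of
its ecological and genetic sub-scores, so genetic knowledge can raise but
never lower the assessed vulnerability.

The IUCN mapper is a deliberately simplified, config-driven engine over
the standard category bounds (criteria A, B2, C, D); unlike the MER it
does not require all criteria, and the overall category is the highest
triggered by any supplied criterion.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "MERAssessment",
    "IUCNAssessment",
    "GeneticVulnerabilityInputs",
    "MER_CATEGORIES",
    "IUCN_CATEGORIES",
    "load_mer_config",
    "load_iucn_config",
    "classify_mer",
    "genetic_sublevel",
    "score_mer",
    "classify_iucn",
    "MER_PRESETS",
    "IUCN_PRESETS",
]

MER_CATEGORIES = ("below-threshold", "Pr", "E", "EE")
IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("issrpop") / "configs" / name
    return yaml.safe_load(ref.read_text())


def load_mer_config(path=None) -> dict:
    if path is None:
        return _load_yaml("mer_criteria.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_iucn_config(path=None) -> dict:
    if path is None:
        return _load_yaml("iucn_thresholds.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class GeneticVulnerabilityInputs:
    """Genetic evidence feeding criterion C.

    ``private_trend`` is the direction of the private-allele count change
    under decline/extinction scenarios; ``chi2_p`` its significance;
    ``scenario_decline`` flags an observed drop of diversity metrics in
    scenario simulations.
    """

    mean_he: float | None = None
    nm: float | None = None
    gst: float | None = None
    private_trend: str = "none"  # decrease | none | increase
    chi2: float | None = None
    chi2_p: float | None = None
    scenario_decline: bool = False

    def __post_init__(self):
        if self.private_trend not in ("decrease", "none", "increase"):
            raise ValueError("private_trend must be decrease/none/increase")


@dataclass
class MERAssessment:
    scores: dict            # criterion -> normalized score
    levels: dict            # criterion -> level name used
    total: float
    category: str
    on_boundary: bool
    genetic_level: str | None = None


@dataclass
class IUCNAssessment:
    inputs: dict
    category: str
    triggered: list = field(default_factory=list)


def classify_mer(total_score: float, config: dict | None = None) -> str:
    """Map a normalized MER total to its risk category (step function)."""
    if total_score < 0:
        raise ValueError("negative MER score")
    th = (config or load_mer_config())["thresholds"]
    if total_score >= th["EE"]:
        return "EE"
    if total_score >= th["E"]:
        return "E"
    if total_score >= th["Pr"]:
        return "Pr"
    return "below-threshold"


def genetic_sublevel(g: GeneticVulnerabilityInputs, config: dict | None = None) -> str:
    """Translate genetic evidence into a criterion-C level name."""
    rules = (config or load_mer_config())["genetic_rules"]
    significant_loss = (
        g.private_trend == "decrease"
        and g.chi2_p is not None
        and g.chi2_p < rules["chi2_p_high_below"]
    )
    if g.scenario_decline or significant_loss:
        return "high"
    if (g.mean_he is not None and g.mean_he < rules["he_medium_below"]) or (
        g.nm is not None and g.nm < rules["nm_medium_below"]
    ):
        return "medium"
    return "low"


def score_mer(
    levels: dict,
    genetic: GeneticVulnerabilityInputs | None = None,
    config: dict | None = None,
) -> MERAssessment:
    """Score the four MER criteria and classify.

    ``levels`` maps each criterion letter A-D to a qualitative level name
    from the config table; all four are required.  With ``genetic`` given,
    criterion C becomes the maximum of the ecological and genetic
    sub-scores.
    """
    config = config or load_mer_config()
    crits = config["criteria"]
    missing = [c for c in "ABCD" if c not in levels]
    if missing:
        raise ValueError(f"MER requires all criteria; missing: {missing}")
    scores, used = {}, {}
    for c in "ABCD":
        table = crits[c]
        level = levels[c]
        if level not in table["levels"]:
            raise ValueError(f"unknown level {level!r} for criterion {c}")
        scores[c] = table["levels"][level] / table["max"]
        used[c] = level
    glevel = None
    if genetic is not None:
        glevel = genetic_sublevel(genetic, config)
        gscore = crits["C"]["levels"][glevel] / crits["C"]["max"]
        if gscore > scores["C"]:
            scores["C"] = gscore
            used["C"] = glevel
    total = sum(scores.values())
    th = config["thresholds"]
    category = classify_mer(total, config)
    on_boundary = any(abs(total - t) < 1e-9 for t in th.values())
    return MERAssessment(
        scores=scores,
        levels=used,
        total=total,
        category=category,
        on_boundary=on_boundary,
        genetic_level=glevel,
    )


def classify_iucn(
    population_size: float | None = None,
    range_area_km2: float | None = None,
    decline_fraction: float | None = None,
    n_locations: int | None = None,
    local_extinction: bool | None = None,
    config: dict | None = None,
) -> IUCNAssessment:
    """Evaluate the supplied criteria against config thresholds.

    At least one input is required.  The overall category is the highest
    triggered; with inputs supplied but nothing triggered the outcome is
    LC (least concern).
    """
    inputs = {
        "population_size": population_size,
        "range_area_km2": range_area_km2,
        "decline_fraction": decline_fraction,
        "n_locations": n_locations,
        "local_extinction": local_extinction,
    }
    if all(v is None for v in inputs.values()):
        raise ValueError("no criteria supplied")
    cfg = config or load_iucn_config()
    triggered = []

    def hit(criterion, cat):
        triggered.append((criterion, cat))

    if decline_fraction is not None:
        for cat in ("CR", "EN", "VU"):
            if decline_fraction >= cfg["A_decline"][cat]:
                hit("A", cat)
                break
    if range_area_km2 is not None:
        for cat in ("CR", "EN", "VU"):
            area_ok = range_area_km2 <= cfg["B2_area_km2"][cat]
            loc_ok = n_locations is None or n_locations <= cfg["B2_locations"][cat]
            if area_ok and loc_ok:
                hit("B2", cat)
                break
    if population_size is not None and decline_fraction is not None and decline_fraction > 0:
        for cat in ("CR", "EN", "VU"):
            if population_size <= cfg["C_population"][cat]:
                hit("C", cat)
                break
    if population_size is not None:
        for cat in ("CR", "EN", "VU"):
            if population_size <= cfg["D_population"][cat]:
                hit("D1", cat)
                break
    if n_locations is not None and n_locations <= cfg["D2_locations"]:
        hit("D2", "VU")
    if local_extinction:
        hit("E", cfg["E_local_extinction"])

    if triggered:
        category = max(
            (c for _, c in triggered), key=IUCN_CATEGORIES.index
        )
    else:
        category = "LC"
    return IUCNAssessment(inputs=inputs, category=category, triggered=triggered)


# ---------------------------------------------------------------------------
# Presets named after the assessment scenarios: year 2005 (basic knowledge),
# 2020 with ecological knowledge (2020e), with 50% individual loss
# (2020e_50), with two local extinctions (2020e_ex), and the same three with
# genetic knowledge added (2020e+g, 2020e+g_50, 2020e+g_ex).  They reproduce
# the assessed categories, not any particular sub-score breakdown.
# ---------------------------------------------------------------------------

_GEN_BASE = GeneticVulnerabilityInputs(mean_he=0.21, nm=0.92, gst=0.47)
_GEN_50 = GeneticVulnerabilityInputs(
    mean_he=0.20, nm=0.92, gst=0.47, private_trend="decrease",
    chi2=15.23, chi2_p=0.02, scenario_decline=True,
)
_GEN_EX = GeneticVulnerabilityInputs(
    mean_he=0.20, nm=0.633, gst=0.47, private_trend="decrease",
    chi2=15.23, chi2_p=0.02, scenario_decline=True,
)

MER_PRESETS = {
    "2005": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "low"},
        "genetic": None,
    },
    "2020e": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "moderate"},
        "genetic": None,
    },
    "2020e_50": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "moderate"},
        "genetic": None,
    },
    "2020e_ex": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "moderate"},
        "genetic": None,
    },
    "2020e+g": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "moderate"},
        "genetic": _GEN_BASE,
    },
    "2020e+g_50": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "moderate"},
        "genetic": _GEN_50,
    },
    "2020e+g_ex": {
        "levels": {"A": "very_restricted", "B": "intermediate", "C": "low", "D": "moderate"},
        "genetic": _GEN_EX,
    },
}

IUCN_PRESETS = {
    "2005": dict(population_size=7000, range_area_km2=0.2, n_locations=6),
    "2020e": dict(population_size=7000, range_area_km2=0.2, n_locations=6),
    "2020e+g": dict(population_size=7000, range_area_km2=0.2, n_locations=6),
    "2020e_50": dict(
        population_size=3500, range_area_km2=0.2, n_locations=6, decline_fraction=0.5
    ),
    "2020e+g_50": dict(
        population_size=3500, range_area_km2=0.2, n_locations=6, decline_fraction=0.5
    ),
    "2020e_ex": dict(
        population_size=3500, range_area_km2=0.15, n_locations=4,
        decline_fraction=0.5, local_extinction=True,
    ),
    "2020e+g_ex": dict(
        population_size=3500, range_area_km2=0.15, n_locations=4,
        decline_fraction=0.5, local_extinction=True,
    ),
}


def assess_preset(method: str, name: str, config: dict | None = None):
    """Run a named preset through the chosen rule engine."""
    if method == "mer":
        preset = MER_PRESETS[name]
        return score_mer(preset["levels"], preset["genetic"], config)
    if method == "iucn":
        return classify_iucn(**IUCN_PRESETS[name], config=config)
    raise ValueError("method must be 'mer' or 'iucn'")
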