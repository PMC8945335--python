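"""End-to-end pipeline orchestration and report bundle writing.

A single :class:`PipelineConfig` drives simulate/ingest -> diversity ->
differentiation -> structure -> scenarios -> risk.  Every stage derives
its own seed from the global seed and the stage name, so stages can be
rerun in isolation, and a run with identical config and seed is
numerically identical.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differentiation import amova_binary, mantel_ibd, nei_gst, pairwise_fst
from .diversity import diversity_summary, estimate_freqs, exact_differentiation_test
from .marker_data import MarkerMatrix, PopulationGeo, read_matrix, write_matrix
from .scenario import ScenarioSpec, apply_scenario, compare_scenarios
from .structure_inference import (
    admixture_mcmc,
    dapc,
    evanno,
    hamming_distances,
    minimum_spanning_network,
    pca,
)
from .synthetic_data import SimDesign, generate, study_preset
from .risk import assess_preset

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline"]

STAGES = ("diversity", "differentiation", "structure", "scenario", "risk")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of the stage name folded into the
    global seed, kept below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class PipelineConfig:
    design: SimDesign | None = None
    input_path: str | None = None
    input_dialect: str = "csv"
    geo: PopulationGeo | None = None
    stages: tuple = STAGES
    n_perm: int = 10000
    mcmc_burnin: int = 2000
    mcmc_samples: int = 5000
    k_min: int = 1
    k_max: int = 5
    k_reps: int = 4
    scenarios: list = field(default_factory=list)
    risk_presets: list = field(default_factory=lambda: ["2020e", "2020e+g"])
    seed: int = 0
    outdir: str = "issrpop_out"

    def __post_init__(self):
        for name, v in (
            ("n_perm", self.n_perm),
            ("mcmc_burnin", self.mcmc_burnin),
            ("mcmc_samples", self.mcmc_samples),
            ("k_reps", self.k_reps),
        ):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a manifest dict.

    All tables go to ``config.outdir`` as TSV/JSON; the manifest records
    inputs, seeds, package version, per-stage runtimes and every file
    written.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written, runtimes, results = [], {}, {}

    def save_tsv(name, df):
        path = out / name
        df.to_csv(path, sep="\t")
        written.append(str(path))

    def save_json(name, payload):
        path = out / name
        path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
        written.append(str(path))

    # -- input ------------------------------------------------------------
    t0 = time.time()
    if config.design is not None:
        m, truth = generate(config.design, seed=derive_seed(config.seed, "simulate"))
        geo = config.design.geo or config.geo
        write_matrix(m, out / "matrix.csv", "csv")
        written.append(str(out / "matrix.csv"))
    elif config.input_path is not None:
        m = read_matrix(config.input_path, config.input_dialect)
        geo = config.geo
    else:
        raise ValueError("config needs a design or an input_path")
    runtimes["input"] = time.time() - t0

    # -- stages -----------------------------------------------------------
    if "diversity" in config.stages:
        t0 = time.time()
        summary = diversity_summary(m)
        table = summary.table.copy()
        table.loc["mean"] = summary.mean
        table.loc["se"] = summary.se
        save_tsv("diversity.tsv", table)
        exact = exact_differentiation_test(
            m, seed=derive_seed(config.seed, "exact_test")
        )
        save_tsv("exact_test.tsv", exact)
        results["diversity"] = summary
        runtimes["diversity"] = time.time() - t0

    if "differentiation" in config.stages:
        t0 = time.time()
        diff = pairwise_fst(m)
        am = amova_binary(
            m, n_perm=config.n_perm, seed=derive_seed(config.seed, "amova")
        )
        save_tsv("amova.tsv", am.table())
        save_tsv("pairwise_fst.tsv", diff.pairwise_fst)
        save_tsv("linearized_fst.tsv", diff.linearized)
        payload = {
            "gst": diff.gst,
            "ht": diff.ht,
            "hs": diff.hs,
            "nm": diff.nm,
            "alpha": diff.alpha,
            "phi_st": am.phi_st,
            "amova_p": am.p_value,
        }
        if geo is not None and len(m.populations) >= 4:
            mr = mantel_ibd(
                diff.linearized,
                geo,
                n_perm=config.n_perm,
                seed=derive_seed(config.seed, "mantel"),
            )
            payload["mantel"] = {
                "r": mr.r,
                "p": mr.p,
                "spearman_rho": mr.spearman_rho,
                "ci95": list(mr.ci95),
            }
        save_json("differentiation.json", payload)
        results["differentiation"] = payload
        runtimes["differentiation"] = time.time() - t0

    if "structure" in config.stages:
        t0 = time.time()
        d = hamming_distances(m)
        net = minimum_spanning_network(d, pop_of=m.pop_of)
        save_tsv(
            "msn_edges.tsv",
            pd.DataFrame(net.edges, columns=["from", "to", "weight"]).set_index("from"),
        )
        ordn = pca(m)
        save_tsv("pca_scores.tsv", ordn.scores.iloc[:, :5])
        dap = dapc(m, seed=derive_seed(config.seed, "dapc"))
        save_tsv("dapc_scores.tsv", dap.scores)
        runs = []
        for K in range(config.k_min, config.k_max + 1):
            for rep in range(config.k_reps):
                run = admixture_mcmc(
                    m,
                    K,
                    n_burnin=config.mcmc_burnin,
                    n_sample=config.mcmc_samples,
                    seed=derive_seed(config.seed, f"admix_K{K}_r{rep}"),
                )
                runs.append(run)
                if rep == 0:
                    save_tsv(f"q_matrix_K{K}.tsv", run.Q)
        ev = evanno(runs)
        save_tsv("evanno.tsv", ev.table)
        results["structure"] = {
            "best_k": ev.best_k,
            "dapc_k": dap.k,
            "pca_pct_1_2": list(ordn.pct_variance[:2]),
        }
        save_json("structure.json", results["structure"])
        runtimes["structure"] = time.time() - t0

    if "scenario" in config.stages:
        t0 = time.time()
        comparisons = {}
        for spec in config.scenarios:
            cmp = compare_scenarios(
                m, spec, n_perm=min(config.n_perm, 1000),
                seed=derive_seed(config.seed, f"scenario_{spec.kind}"),
            )
            name = spec.kind if spec.kind != "none" else "identity"
            comparisons[name] = {
                "chi2": cmp.chi2,
                "chi2_df": cmp.chi2_df,
                "chi2_p": cmp.chi2_p,
                "baseline_gst": cmp.baseline_gst,
                "perturbed_gst": cmp.perturbed_gst,
                "baseline_nm": cmp.baseline_nm,
                "perturbed_nm": cmp.perturbed_nm,
                "baseline_pct_among": cmp.baseline_amova.pct_among,
                "perturbed_pct_among": cmp.perturbed_amova.pct_among,
                "baseline_mean_he": cmp.baseline_diversity.mean["He"],
                "perturbed_mean_he": cmp.perturbed_diversity.mean["He"],
                "private_before": cmp.private_before,
                "private_after": cmp.private_after,
            }
        if comparisons:
            save_json("scenarios.json", comparisons)
        results["scenario"] = comparisons
        runtimes["scenario"] = time.time() - t0

    if "risk" in config.stages:
        t0 = time.time()
        risk_out = {}
        for preset in config.risk_presets:
            mer = assess_preset("mer", preset)
            iucn = assess_preset("iucn", preset)
            risk_out[preset] = {
                "mer_total": mer.total,
                "mer_category": mer.category,
                "iucn_category": iucn.category,
                "iucn_triggered": iucn.triggered,
            }
        save_json("risk.json", risk_out)
        results["risk"] = risk_out
        runtimes["risk"] = time.time() - t0

    manifest = {
        "package": "issrpop",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in config.stages},
        "n_individuals": m.n_individuals,
        "n_loci": m.n_loci,
        "populations": m.populations,
        "stages": list(config.stages),
        "runtimes_s": runtimes,
        "files": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    manifest["results"] = results
    return manifest
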