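"""End-to-end orchestration: simulate -> phenotype -> associate -> meta.

Each stage reads/writes plain CSV/TSV/JSON under an output directory and
emits a run manifest (command, config hash, seed, input/output paths, tool
version). Stages are deterministic given config + seed, so re-running a
manifest reproduces its data outputs byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .association import backward_eliminate, estimate_maf_and_hwe, fit_logistic
from .config import RulesConfig, SimulationConfig, dump_config
from .meta_analysis import load_studies, make_forest_table, pool_fixed_effects
from .phenotyping import build_analysis_table, classify_cohort
from .simulate import RECORDS_END, simulate_observational_cohort

logger = logging.getLogger(__name__)

#: Candidate covariates offered to the stepwise-adjusted model per phenotype.
ADJUSTMENT_TERMS = {
    "gsi": ["first_statin_simva", "mean_equiv_dose", "age", "female", "comedication"],
    "ldi": ["first_statin_simva", "last_statin_simva", "log10_ck", "comedication"],
}


def run_simulate(
    sim: SimulationConfig,
    rules: RulesConfig,
    out_dir,
    genotype_format: str = "csv",
) -> dict[str, str]:
    bundle = simulate_observational_cohort(sim, rules)
    paths = io.write_bundle(bundle, out_dir, genotype_format=genotype_format)
    manifest = io.write_manifest(
        out_dir, "simulate", io.config_hash(dump_config(sim, rules)), sim.seed, [], list(paths.values())
    )
    paths["manifest"] = manifest
    return paths


def run_phenotype(in_dir, out_dir, rules: RulesConfig, seed: int = 0) -> dict[str, str]:
    bundle = io.read_bundle(in_dir)
    assignments = classify_cohort(
        bundle.prescriptions, bundle.labs, bundle.patients, rules, bundle.records_end
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "assignments.csv"
    assignments.to_csv(path, index=False)
    manifest = io.write_manifest(
        out,
        "phenotype",
        io.config_hash(dump_config(SimulationConfig(), rules)),
        seed,
        [str(Path(in_dir))],
        [str(path)],
    )
    return {"assignments": str(path), "manifest": manifest}


def run_associate(
    in_dir,
    assignments_path,
    out_dir,
    phenotype: str,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Unadjusted and stepwise-adjusted dominant-model logistic association."""
    bundle = io.read_bundle(in_dir)
    assignments = pd.read_csv(assignments_path)
    table = build_analysis_table(assignments, bundle.genotypes, bundle.patients, phenotype)
    maf, hwe_p = estimate_maf_and_hwe(bundle.genotypes)

    unadjusted = fit_logistic(table, terms=[])
    # constant or all-missing covariates carry no information and break the fit
    terms = [
        t
        for t in ADJUSTMENT_TERMS[phenotype]
        if t in table.columns and table[t].dropna().nunique() > 1
    ]
    retained, adjusted, trace = backward_eliminate(
        table, terms, forced_terms=("genotype_dom",), alpha=alpha
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / f"analysis_table_{phenotype}.csv"
    table.to_csv(table_path, index=False)
    report = {
        "phenotype": phenotype,
        "n": int(len(table)),
        "n_cases": int(table["outcome"].sum()),
        "n_controls": int((1 - table["outcome"]).sum()),
        "maf": maf,
        "hwe_p": hwe_p,
        "stepwise_alpha": alpha,
        "unadjusted": unadjusted.to_dict(),
        "adjusted": adjusted.to_dict(),
        "retained_terms": [t for t in retained],
        "elimination_trace": [{"term": t, "p": p} for t, p in trace],
    }
    report_path = out / f"association_{phenotype}.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    io.write_manifest(
        out,
        f"associate-{phenotype}",
        io.config_hash(dump_config(SimulationConfig(), RulesConfig())),
        seed,
        [str(Path(in_dir)), str(assignments_path)],
        [str(table_path), str(report_path)],
    )
    return report


def run_meta(out_dir, studies_path=None, seed: int = 0) -> dict:
    """Pool per-study odds ratios; writes the forest table and a JSON report."""
    effects = load_studies(studies_path)
    result = pool_fixed_effects(effects)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    forest = make_forest_table(effects, result)
    forest_path = out / "forest_table.tsv"
    forest.to_csv(forest_path, sep="\t", index=False)
    meta_path = out / "meta_result.json"
    with open(meta_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    io.write_manifest(
        out,
        "meta",
        io.config_hash("studies:" + (str(studies_path) or "packaged")),
        seed,
        [str(studies_path)] if studies_path else [],
        [str(forest_path), str(meta_path)],
    )
    return result.to_dict()


def run_all(
    sim: SimulationConfig,
    rules: RulesConfig,
    out_dir,
    genotype_format: str = "csv",
    studies_path=None,
) -> dict:
    out = Path(out_dir)
    run_simulate(sim, rules, out, genotype_format=genotype_format)
    run_phenotype(out, out, rules, seed=sim.seed)
    reports = {}
    for phen in ("gsi", "ldi"):
        reports[phen] = run_associate(
            out, out / "assignments.csv", out, phen, seed=sim.seed
        )
    reports["meta"] = run_meta(out, studies_path, seed=sim.seed)
    return reports
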