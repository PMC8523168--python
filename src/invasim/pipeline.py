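"""Configuration-driven orchestration of the full analysis chain.

Stages run in order: simulate (or load) -> preprocess -> diversity ->
reduce -> rf -> sem -> sensitivity.  Every stage writes its artifacts
under the output directory and the run ends with a manifest (content
hashes, seeds, per-stage runtimes) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (INVADERS, PRODUCTIVITY_COLUMNS, TIMEPOINTS, InvasionTable,
                   write_otu_table, write_results)
from .dimreduce import run_all_reductions
from .diversity import diversity_table
from .preprocess import (TransformSpec, average_replicates, convert_and_flag,
                         filter_otu_table)
from .rf import assemble_features, compare_reductions, rf_variable_importance
from .sem import build_mediation_models, compare_models, fit_sem, \
    mediation_decomposition
from .sensitivity import run_sensitivity
from .simulate import SynthConfig, calibration_models, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "diversity", "reduce", "rf", "sem",
          "sensitivity")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the emulated study design."""

    simulate: SynthConfig = field(default_factory=SynthConfig)
    outdir: str = "invasim_run"
    seed: int = 0
    # preprocess
    min_sample_prevalence: int = 10
    min_total_reads: int = 100
    min_community_reads: int = 10000
    detection_threshold_lux: float = 12.0
    # reduce
    k_pcoa: int = 5
    r_threshold: float = 0.2
    p_threshold: float = 0.01
    min_group_size: int = 3
    sparcc_bootstrap: int = 100
    # rf
    n_trees: int = 500
    run_reduction_comparison: bool = False
    # sensitivity
    n_perm: int = 999
    sensitivity_scope: str = "column"
    normalize_rao: bool = True

    def validate(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.k_pcoa < 1:
            raise ValueError("k_pcoa must be >= 1")
        if not 0 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in [0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fan-out (documented derivation)."""
        return (self.seed * 1009 + STAGES.index(stage)) % (2 ** 31)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    t_all = time.time()

    def stage_done(name: str, t0: float, files: list[Path]):
        manifest["stages"][name] = {
            "runtime_s": round(time.time() - t0, 3),
            "files": {str(p.relative_to(outdir)): _hash_file(p) for p in files},
        }

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    sim_cfg = config.simulate
    sim_cfg.seed = config.stage_seed("simulate")
    data = simulate_dataset(sim_cfg)
    table, tree = data["otu_table"], data["tree"]
    phenotypes, invasion = data["phenotypes"], data["invasion"]
    truth = data["ground_truth"]
    sim_dir = outdir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    write_otu_table(table, sim_dir / "otu_counts.tsv", sim_dir / "taxonomy.tsv")
    tree.write(str(sim_dir / "tree.nwk"))
    files = write_results({"ground_truth": truth.summary()}, sim_dir)
    phenotypes.values.to_csv(sim_dir / "phenotypes.csv", index_label="community")
    invasion.data.to_csv(sim_dir / "invasion_raw.csv", index=False)
    stage_done("simulate", t0, files + [sim_dir / "otu_counts.tsv",
                                        sim_dir / "taxonomy.tsv",
                                        sim_dir / "tree.nwk",
                                        sim_dir / "phenotypes.csv",
                                        sim_dir / "invasion_raw.csv"])

    # --- preprocess ---------------------------------------------------
    t0 = time.time()
    filtered = filter_otu_table(table, config.min_sample_prevalence,
                                config.min_total_reads,
                                config.min_community_reads)
    cals = calibration_models(sim_cfg)
    converted = convert_and_flag(invasion, cals, config.detection_threshold_lux)
    averaged = average_replicates(converted)
    pre_dir = outdir / "preprocess"
    endpoints = averaged.endpoint_wide()
    flags = averaged.flags_wide()
    files = write_results({"endpoints_cells": endpoints,
                           "below_detection": flags.astype(int)}, pre_dir)
    stage_done("preprocess", t0, files)

    # --- diversity ----------------------------------------------------
    t0 = time.time()
    invader_tips = [f"INV_{inv}" for inv in INVADERS]
    div = diversity_table(filtered, tree, invader_tips,
                          normalize_rao=config.normalize_rao)
    div = div.rename(columns={f"invader_distance_INV_{inv}":
                              f"invader_distance_{inv}" for inv in INVADERS})
    files = write_results({"diversity": div}, outdir / "diversity")
    stage_done("diversity", t0, files)

    # --- reduce -------------------------------------------------------
    t0 = time.time()
    reductions = run_all_reductions(
        filtered, k_pcoa=config.k_pcoa, r_threshold=config.r_threshold,
        p_threshold=config.p_threshold, min_group_size=config.min_group_size,
        n_bootstrap=config.sparcc_bootstrap, seed=config.stage_seed("reduce"))
    red_dir = outdir / "reduce"
    bundle = {f"features_{name}": t for name, t in reductions.tables.items()}
    part = reductions.metadata["functional_groups"].pop("partition")
    bundle["partition"] = pd.DataFrame(
        sorted(part.items()), columns=["otu_id", "group_id"])
    bundle["reduction_metadata"] = reductions.metadata
    files = write_results(bundle, red_dir)
    stage_done("reduce", t0, files)

    # --- rf -----------------------------------------------------------
    t0 = time.time()
    spec = TransformSpec()
    group_feats = reductions["functional_groups"]
    rf_dir = outdir / "rf"
    rf_bundle: dict = {}
    responses = {}
    pseudo_r2 = {}
    for inv in INVADERS:
        X = assemble_features(group_feats.loc[endpoints.index], phenotypes,
                              div.loc[endpoints.index], inv, transform=spec)
        for t in TIMEPOINTS:
            col = f"{inv}.cells.{t}"
            y = pd.Series(spec.transform_response(endpoints[col]),
                          index=endpoints.index)
            res = rf_variable_importance(X, y, n_trees=config.n_trees,
                                         seed=config.stage_seed("rf"))
            rf_bundle[f"importance_{inv}_{t}h"] = res.importance
            pseudo_r2[col] = res.pseudo_r2
            responses[(inv, t)] = y
    rf_bundle["pseudo_r2"] = pseudo_r2
    if config.run_reduction_comparison:
        rf_bundle["reduction_comparison"] = compare_reductions(
            {k: v.loc[endpoints.index] for k, v in reductions.tables.items()},
            responses, n_trees=config.n_trees, seed=config.stage_seed("rf"))
    files = write_results(rf_bundle, rf_dir)
    stage_done("rf", t0, files)

    # --- sem ----------------------------------------------------------
    t0 = time.time()
    comp_tx = spec.transform_explanatory(group_feats.loc[endpoints.index])
    comp_tx["simpson"] = div.loc[endpoints.index, "simpson"]
    constant = comp_tx.columns[comp_tx.std() < 1e-12]
    if len(constant):
        logger.info("sem: dropping constant indicators %s", list(constant))
        comp_tx = comp_tx.drop(columns=constant)
    prod_tx = spec.transform_explanatory(
        phenotypes.values.loc[endpoints.index, list(PRODUCTIVITY_COLUMNS)])
    inv_tx = endpoints.apply(spec.transform_response)
    sem_data = pd.concat([comp_tx, prod_tx, inv_tx], axis=1)
    specs = build_mediation_models(list(comp_tx.columns), list(prod_tx.columns),
                                   list(inv_tx.columns))
    fits = {name: fit_sem(m, sem_data, seed=config.stage_seed("sem"))
            for name, m in specs.items()}
    cmp_res = compare_models(fits)
    dec = mediation_decomposition(fits["partial_mediation"])
    sem_bundle = {"model_comparison": cmp_res["table"],
                  "lrt_partial_vs_complete": cmp_res.get("lrt", {}),
                  "mediation": dec.summary()}
    for name, f in fits.items():
        sem_bundle[f"fit_{name}"] = {
            "chi2": f.chi2, "df": f.df, "aicc": f.aicc, "cfi": f.cfi,
            "std_paths": {f"{s}->{d}": v for (s, d), v in f.std_paths.items()},
            "heywood": f.heywood,
        }
    files = write_results(sem_bundle, outdir / "sem")
    stage_done("sem", t0, files)

    # --- sensitivity ----------------------------------------------------
    t0 = time.time()
    other = pd.concat([comp_tx, prod_tx], axis=1)
    sens = run_sensitivity(endpoints, flags, specs, other,
                           transform=spec.transform_response,
                           n_perm=config.n_perm,
                           seed=config.stage_seed("sensitivity"),
                           scope=config.sensitivity_scope)
    sens_bundle = {
        "sensitivity": {
            "n_permutations": sens.n_permutations,
            "n_dropped": sens.n_dropped,
            "best_model_freq_pct": sens.best_model_freq,
            "mean_delta_aicc": sens.mean_delta_aicc,
            "mean_abs_aicc_shift": sens.mean_abs_aicc_shift,
            "unpermuted_best": sens.unpermuted_best,
        },
        "per_permutation_aicc": sens.per_permutation,
    }
    files = write_results(sens_bundle, outdir / "sensitivity")
    stage_done("sensitivity", t0, files)

    manifest["runtime_s"] = round(time.time() - t_all, 3)
    manifest["ground_truth"] = truth.summary()
    manifest["recovered_proportion_mediated"] = dec.proportion_mediated
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return manifest
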