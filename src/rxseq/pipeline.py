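"""End-to-end orchestration: (simulate) -> build -> select-K -> assign -> profile.

One global seed is expanded into per-stage seeds with a fixed scheme
(``numpy.random.default_rng([seed, stage_index])``), so any stage can be
rerun in isolation and the whole run is deterministic for a given config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mixture import posterior_assign, save_model
from .profiles import (
    cdai_yearly_means,
    profile_clusters,
    profiles_to_records,
    read_visits,
)
from .selection import select_k
from .sequences import (
    build_all,
    read_diagnoses,
    read_prescriptions,
    write_exclusions,
    write_sequences,
)
from .synthetic import preset_scenario, simulate_cohort, write_cohort
from .types import FilterConfig, parse_date

logger = logging.getLogger("rxseq.pipeline")

_STAGE_INDEX = {"simulate": 0, "fit": 1}


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.default_rng([seed, _STAGE_INDEX[stage]]).integers(2**31))


def _log(stage: str, **fields) -> None:
    logger.info(json.dumps({"stage": stage, **fields}, default=str))


def _config_hash(config: dict) -> str:
    semantic = {k: v for k, v in config.items() if k != "output_dir"}
    canon = json.dumps(semantic, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _filter_config(block: dict | None) -> FilterConfig:
    block = dict(block or {})
    for key in ("study_start", "end_date"):
        if block.get(key) is not None:
            block[key] = parse_date(block[key])
    if "ra_code_prefixes" in block:
        block["ra_code_prefixes"] = tuple(block["ra_code_prefixes"])
    return FilterConfig(**block)


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline from a config dict; returns the manifest."""
    if "seed" not in config:
        raise ValueError("config must set a seed")
    seed = int(config["seed"])
    outdir = Path(config.get("output_dir", "rxseq_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    has_inputs = "inputs" in config
    has_sim = "simulate" in config
    if has_inputs == has_sim:
        raise ValueError("config needs exactly one of 'inputs' or 'simulate'")

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "rxseq_version": __version__,
        "stages": {},
    }

    # -- stage: inputs ------------------------------------------------------
    if has_sim:
        sim = dict(config["simulate"])
        preset = sim.pop("preset", "paper_default")
        n = int(sim.pop("n_patients", sim.pop("n", 2000)))
        cfg = preset_scenario(
            preset, seed=_stage_seed(seed, "simulate"), n_patients=n, **sim
        )
        cohort = simulate_cohort(cfg)
        write_cohort(cohort, outdir)
        prescriptions = cohort.prescriptions
        diagnoses = cohort.diagnoses
        visits = cohort.visits
        _log("simulate", n_patients=n, preset=preset,
             n_prescriptions=len(prescriptions))
        manifest["stages"]["simulate"] = {
            "preset": preset,
            "n_patients": n,
            "n_prescriptions": len(prescriptions),
        }
    else:
        paths = config["inputs"]
        prescriptions = read_prescriptions(paths["prescriptions"])
        diagnoses = read_diagnoses(paths["diagnoses"])
        visits = read_visits(paths["visits"]) if paths.get("visits") else []
        _log("inputs", n_prescriptions=len(prescriptions))
        manifest["stages"]["inputs"] = {
            "n_prescriptions": len(prescriptions),
            "n_diagnoses": len(diagnoses),
            "n_visits": len(visits),
        }

    # -- stage: sequences ---------------------------------------------------
    fconf = _filter_config(config.get("filter"))
    sequences, summary = build_all(prescriptions, diagnoses, config=fconf)
    if not sequences:
        raise RuntimeError("sequence_builder: no eligible patients")
    write_sequences(sequences, outdir / "sequences.csv")
    write_exclusions(summary.exclusions, outdir / "exclusions.csv")
    _log("build_sequences", n_eligible=summary.n_eligible,
         n_unique=summary.n_unique_sequences)
    manifest["stages"]["build_sequences"] = {
        "n_input_patients": summary.n_input_patients,
        "n_eligible": summary.n_eligible,
        "n_prescriptions": summary.n_prescriptions,
        "n_unique_sequences": summary.n_unique_sequences,
    }

    # -- stage: model selection + fit --------------------------------------
    fit_opts = dict(config.get("fit", {}))
    table = select_k(
        sequences,
        k_candidates=fit_opts.get("k_candidates", [2, 3, 4, 5]),
        n_restarts=int(fit_opts.get("n_restarts", 20)),
        tol=float(fit_opts.get("tol", 1e-8)),
        max_iter=int(fit_opts.get("max_iter", 500)),
        pseudocount=float(fit_opts.get("pseudocount", 1e-6)),
        seed=_stage_seed(seed, "fit"),
        window_days=fconf.window_days,
    )
    table.to_frame().to_csv(outdir / "selection.csv", index=False)
    best = table.best_fit
    save_model(best, outdir / "model.json")
    _log("select_k", selected_k=table.selected_k, ch_best_k=table.ch_best_k,
         ch_agrees=table.ch_agrees)
    manifest["stages"]["select_k"] = {
        "selected_k": table.selected_k,
        "ch_best_k": table.ch_best_k,
        "ch_agrees": table.ch_agrees,
        "log_likelihood": best.log_likelihood,
    }

    # -- stage: assignment --------------------------------------------------
    assignments = posterior_assign(sequences, best.params)
    adf = pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "cluster": a.cluster,
                **{f"p_{k + 1}": a.posterior[k] for k in range(best.params.K)},
            }
            for a in assignments
        ]
    )
    adf.to_csv(outdir / "assignments.csv", index=False)
    sizes = adf["cluster"].value_counts().sort_index().to_dict()
    _log("assign", cluster_sizes=sizes)
    manifest["stages"]["assign"] = {"cluster_sizes": {str(k): int(v) for k, v in sizes.items()}}

    # -- stage: profiles ----------------------------------------------------
    profiles = profile_clusters(sequences, assignments)
    (outdir / "profiles.json").write_text(
        json.dumps(profiles_to_records(profiles), indent=2)
    )
    traj = cdai_yearly_means(visits, sequences, assignments)
    traj.to_csv(outdir / "cdai_trajectories.csv", index=False)
    _log("profile", n_clusters=len(profiles))
    manifest["stages"]["profile"] = {
        "n_clusters": len(profiles),
        "n_trajectory_cells": int(traj["n"].sum()),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
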