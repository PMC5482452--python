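"""End-to-end pipeline: simulate/load -> fit -> select -> validate -> overlap.

All randomness flows from a single master seed through a documented
derivation rule (BLAKE2 hash of the stage name mixed with the master seed),
so reruns with an identical configuration reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from spatocc import __version__
from spatocc.evaluate import cross_validate, enumerate_candidates, select_model
from spatocc.grid import build_grid
from spatocc.io import (
    read_site_dataset,
    read_traffic_dataset,
    write_site_dataset,
    write_surface_csv,
    write_traffic_dataset,
)
from spatocc.mcmc import (
    MCMCConfig,
    ModelSpec,
    compute_dic,
    ecological_design,
    fit_binomial_icar,
    fit_site_occupancy_icar,
    predict_surface,
)
from spatocc.overlap import compare_surfaces
from spatocc.synthetic import simulate_occupancy_dataset, simulate_traffic_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the master seed."""
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _mcmc_config(cfg: dict, seed: int) -> MCMCConfig:
    return MCMCConfig(
        n_iter=int(cfg.get("n_iter", 10_000)),
        burn_in=int(cfg.get("burn_in", 5_000)),
        thin=int(cfg.get("thin", 5)),
        n_chains=int(cfg.get("n_chains", 2)),
        seed=seed,
    )


def validate_config(config: dict) -> None:
    """Fail fast on structural problems before any compute."""
    if "master_seed" not in config:
        raise PipelineError("validate", "missing-seed", "config needs a master_seed")
    if "grid" not in config or "bbox" not in config["grid"]:
        raise PipelineError("validate", "missing-grid", "config needs grid.bbox")
    sim = config.get("simulate", {})
    cov_names = list(sim.get("covariate_names", []))
    for sp_name, sp_cfg in sim.get("species", {}).items():
        if len(sp_cfg.get("beta", [])) != len(cov_names) + 1:
            raise PipelineError(
                "validate",
                "beta-shape",
                f"species {sp_name}: beta must have {len(cov_names) + 1} entries",
            )
    search = config.get("model_search", {})
    for name in search.get("covariates", cov_names):
        if cov_names and name not in cov_names:
            raise PipelineError(
                "validate", "unknown-covariate", f"unknown covariate {name!r}"
            )
    for pair in config.get("overlap_pairs", []):
        if len(pair) != 2:
            raise PipelineError(
                "validate", "bad-overlap-pair", f"overlap pair {pair!r} must have 2 names"
            )


def simulate_stage(config: dict, outdir: Path) -> dict[str, Path]:
    """Generate all configured synthetic datasets under ``outdir``."""
    master = int(config["master_seed"])
    gcfg = config["grid"]
    grid = build_grid(
        tuple(gcfg["bbox"]), float(gcfg["cell_size"]), gcfg.get("scheme", "queen")
    )
    sim = config.get("simulate", {})
    cov_names = tuple(sim.get("covariate_names", ()))
    written = {}
    for sp_name, sp_cfg in sim.get("species", {}).items():
        seed = derive_seed(master, f"simulate:{sp_name}")
        data, truth = simulate_occupancy_dataset(
            grid,
            beta=np.asarray(sp_cfg["beta"], dtype=float),
            gamma=np.asarray(sp_cfg["gamma"], dtype=float),
            V_rho=float(sp_cfg.get("V_rho", 0.0)),
            visits_per_cell=sp_cfg.get("visits_per_cell"),
            seed=seed,
            covariate_names=cov_names or None,
        )
        paths = write_site_dataset(data, outdir / sp_name, truth=truth, seed=seed)
        written[sp_name] = paths["sites"].parent
    if "traffic" in sim:
        tcfg = sim["traffic"]
        seed = derive_seed(master, "simulate:traffic")
        tdata, _ = simulate_traffic_dataset(
            grid,
            beta=np.asarray(tcfg["beta"], dtype=float),
            V_rho=float(tcfg.get("V_rho", 0.0)),
            seed=seed,
            covariate_names=tuple(tcfg.get("covariate_names", ("dist_coast",))),
        )
        paths = write_traffic_dataset(tdata, outdir / "traffic")
        written["traffic"] = paths["cells"].parent
    return written


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full analysis and write a reproducibility manifest."""
    t0 = time.time()
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(config["master_seed"])
    manifest: dict = {
        "version": __version__,
        "master_seed": master,
        "stages": [],
        "artifacts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    # --- stage: simulate (or reuse pre-existing dataset dirs)
    data_dir = outdir / "data"
    try:
        dataset_dirs = simulate_stage(config, data_dir)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", "failed", str(exc)) from exc
    manifest["stages"].append("simulate")

    search = config.get("model_search", {})
    mcmc_cfg = config.get("mcmc", {})
    cv_cfg = config.get("cv", {})
    surfaces: dict[str, Path] = {}
    selection_rows = []
    cv_report: dict[str, dict] = {}

    species_names = [n for n in dataset_dirs if n != "traffic"]
    for sp_name in species_names:
        data = read_site_dataset(dataset_dirs[sp_name])
        cov_names = [n for n in data.x_names if n != "intercept"]
        det_terms = tuple(n for n in data.w_names if n != "intercept")
        candidates = enumerate_candidates(
            search.get("covariates", cov_names),
            max_interactions=int(search.get("max_interactions", 0)),
            cap=int(search.get("cap", 64)),
            include_intercept_only=bool(search.get("include_intercept_only", True)),
            detection_terms=det_terms,
        )
        fits = []
        for k, spec in enumerate(candidates):
            seed = derive_seed(master, f"fit:{sp_name}:{k}")
            try:
                post = fit_site_occupancy_icar(data, spec, _mcmc_config(mcmc_cfg, seed))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("fit-occupancy", "mcmc-failed", f"{sp_name}: {exc}") from exc
            dic, dbar, pd_eff = compute_dic(post, data)
            fits.append((spec, dic, post))
            selection_rows.append(
                {
                    "dataset": sp_name,
                    "terms": spec.term_label(),
                    "DIC": dic,
                    "Dbar": dbar,
                    "pD": pd_eff,
                }
            )
        best = select_model([(s, d) for s, d, _ in fits])
        best_post = next(p for s, d, p in fits if s is best)
        logger.info("%s: selected terms %s", sp_name, best.term_label())

        X_best, _ = ecological_design(data, best)
        surface = predict_surface(best_post, X_best, grid=data.grid)
        spath = write_surface_csv(surface, data.grid, outdir / f"surface_{sp_name}.csv")
        surfaces[sp_name] = spath
        record(f"surface_{sp_name}", spath)

        if cv_cfg.get("enabled", True):
            seed = derive_seed(master, f"cv:{sp_name}")
            cv = cross_validate(
                data,
                best,
                repeats=int(cv_cfg.get("repeats", 10)),
                train_frac=float(cv_cfg.get("train_frac", 0.75)),
                seed=seed,
                mcmc=_mcmc_config(cv_cfg.get("mcmc", mcmc_cfg), seed),
            )
            cv_report[sp_name] = cv.to_dict()
    manifest["stages"] += ["fit-occupancy", "select", "predict"]

    if "traffic" in dataset_dirs:
        tdata = read_traffic_dataset(dataset_dirs["traffic"])
        cov_names = [n for n in tdata.x_names if n != "intercept"]
        candidates = enumerate_candidates(
            cov_names,
            max_interactions=int(search.get("max_interactions", 0)),
            cap=int(search.get("cap", 64)),
            include_intercept_only=bool(search.get("include_intercept_only", True)),
        )
        fits = []
        for k, spec in enumerate(candidates):
            seed = derive_seed(master, f"fit:traffic:{k}")
            post = fit_binomial_icar(tdata, spec, _mcmc_config(mcmc_cfg, seed))
            dic, dbar, pd_eff = compute_dic(post, tdata)
            fits.append((spec, dic, post))
            selection_rows.append(
                {"dataset": "traffic", "terms": spec.term_label(), "DIC": dic,
                 "Dbar": dbar, "pD": pd_eff}
            )
        best = select_model([(s, d) for s, d, _ in fits])
        best_post = next(p for s, d, p in fits if s is best)
        X_best, _ = ecological_design(tdata, best)
        surface = predict_surface(best_post, X_best, grid=tdata.grid)
        spath = write_surface_csv(surface, tdata.grid, outdir / "surface_traffic.csv")
        surfaces["traffic"] = spath
        record("surface_traffic", spath)
        manifest["stages"].append("fit-traffic")

    sel_path = outdir / "model_selection.csv"
    pd.DataFrame(selection_rows).to_csv(sel_path, index=False, encoding="utf-8",
                                        float_format="%.10g")
    record("model_selection", sel_path)

    if cv_report:
        cv_path = outdir / "cv_report.json"
        cv_path.write_text(json.dumps(cv_report, indent=2), encoding="utf-8")
        record("cv_report", cv_path)
        manifest["stages"].append("cv")

    overlap_report = {}
    from spatocc.io import read_surface_csv

    for pair in config.get("overlap_pairs", []):
        a, b = pair
        if a not in surfaces or b not in surfaces:
            raise PipelineError(
                "overlap", "unknown-surface", f"overlap pair ({a}, {b}) not available"
            )
        res = compare_surfaces(read_surface_csv(surfaces[a]), read_surface_csv(surfaces[b]))
        rec = res.to_dict()
        rec["inputs"] = [str(surfaces[a].name), str(surfaces[b].name)]
        overlap_report[f"{a}|{b}"] = rec
    if overlap_report:
        op = outdir / "overlap_report.json"
        op.write_text(json.dumps(overlap_report, indent=2), encoding="utf-8")
        record("overlap_report", op)
        manifest["stages"].append("overlap")

    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
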