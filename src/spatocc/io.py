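"""Plain-text readers and writers for datasets, surfaces and reports.

Dataset directory dialect (UTF-8 CSV, ``.`` decimal separator):

- ``grid.json`` — origin, cell_size, n_rows, n_cols, adjacency scheme;
- ``sites.csv`` — ``cell_id, x, y, <covariate columns>``;
- ``visits.csv`` — ``cell_id, visit_index, <detection columns>, detected``;
- ``truth.json`` — simulation parameters, when the data are synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spatocc.grid import GridError, LatticeGrid, SiteDataset, build_grid
from spatocc.mcmc import PredictionSurface
from spatocc.synthetic import SimulationTruth, TrafficDataset


def write_site_dataset(
    data: SiteDataset,
    outdir: str | Path,
    truth: SimulationTruth | None = None,
    seed: int | None = None,
    scheme: str = "queen",
) -> dict[str, Path]:
    """Write a dataset directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    grid_meta = {
        "origin": list(data.grid.origin),
        "cell_size": data.grid.cell_size,
        "n_rows": data.grid.n_rows,
        "n_cols": data.grid.n_cols,
        "scheme": scheme,
    }
    paths["grid"] = outdir / "grid.json"
    paths["grid"].write_text(json.dumps(grid_meta, indent=2), encoding="utf-8")

    centers = data.grid.cell_centers()
    sites = pd.DataFrame({"cell_id": data.grid.cell_ids, "x": centers[:, 0], "y": centers[:, 1]})
    for j, name in enumerate(data.x_names):
        if name == "intercept":
            continue
        sites[name] = data.X[:, j]
    paths["sites"] = outdir / "sites.csv"
    sites.to_csv(paths["sites"], index=False, encoding="utf-8")

    visit_index = np.concatenate(
        [np.arange(v) for v in data.visits if v > 0]
    ) if data.n_visits else np.empty(0, dtype=int)
    visits = pd.DataFrame({"cell_id": data.visit_cell, "visit_index": visit_index})
    for j, name in enumerate(data.w_names):
        if name == "intercept":
            continue
        visits[name] = data.W[:, j]
    visits["detected"] = data.y
    paths["visits"] = outdir / "visits.csv"
    visits.to_csv(paths["visits"], index=False, encoding="utf-8")

    if truth is not None:
        payload = {
            "beta": truth.beta.tolist(),
            "gamma": truth.gamma.tolist(),
            "V_rho": truth.V_rho,
            "seed": seed,
        }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return paths


def read_site_dataset(indir: str | Path) -> SiteDataset:
    """Read a dataset directory written by :func:`write_site_dataset`."""
    indir = Path(indir)
    meta = json.loads((indir / "grid.json").read_text(encoding="utf-8"))
    x0, y0 = meta["origin"]
    cs = meta["cell_size"]
    bbox = (x0, y0, x0 + meta["n_cols"] * cs, y0 + meta["n_rows"] * cs)
    grid = build_grid(bbox, cs, scheme=meta.get("scheme", "queen"))

    sites = pd.read_csv(indir / "sites.csv")
    if len(sites) != grid.n_cells:
        raise GridError("sites.csv row count does not match the grid")
    sites = sites.sort_values("cell_id").reset_index(drop=True)
    cov_cols = [c for c in sites.columns if c not in ("cell_id", "x", "y")]
    X = np.column_stack([np.ones(grid.n_cells)] + [sites[c].to_numpy(float) for c in cov_cols])

    visits = pd.read_csv(indir / "visits.csv")
    det_cols = [c for c in visits.columns if c not in ("cell_id", "visit_index", "detected")]
    n_visits = len(visits)
    W = np.column_stack(
        [np.ones(n_visits)] + [visits[c].to_numpy(float) for c in det_cols]
    ) if n_visits else np.ones((0, 1 + len(det_cols)))
    visit_cell = visits["cell_id"].to_numpy(np.int64) if n_visits else np.empty(0, np.int64)
    counts = np.bincount(visit_cell, minlength=grid.n_cells)
    return SiteDataset(
        grid=grid,
        X=X,
        x_names=("intercept", *cov_cols),
        W=W,
        w_names=("intercept", *det_cols),
        y=visits["detected"].to_numpy(np.int64) if n_visits else np.empty(0, np.int64),
        visit_cell=visit_cell,
        visits=counts,
    )


def write_traffic_dataset(data: TrafficDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    grid_meta = {
        "origin": list(data.grid.origin),
        "cell_size": data.grid.cell_size,
        "n_rows": data.grid.n_rows,
        "n_cols": data.grid.n_cols,
        "scheme": "queen",
    }
    paths["grid"] = outdir / "grid.json"
    paths["grid"].write_text(json.dumps(grid_meta, indent=2), encoding="utf-8")
    centers = data.grid.cell_centers()
    df = pd.DataFrame(
        {
            "cell_id": data.grid.cell_ids,
            "x": centers[:, 0],
            "y": centers[:, 1],
            "trials": data.trials,
            "successes": data.successes,
        }
    )
    for j, name in enumerate(data.x_names):
        if name == "intercept":
            continue
        df[name] = data.X[:, j]
    paths["cells"] = outdir / "cells.csv"
    df.to_csv(paths["cells"], index=False, encoding="utf-8")
    return paths


def read_traffic_dataset(indir: str | Path) -> TrafficDataset:
    indir = Path(indir)
    meta = json.loads((indir / "grid.json").read_text(encoding="utf-8"))
    x0, y0 = meta["origin"]
    cs = meta["cell_size"]
    bbox = (x0, y0, x0 + meta["n_cols"] * cs, y0 + meta["n_rows"] * cs)
    grid = build_grid(bbox, cs, scheme=meta.get("scheme", "queen"))
    df = pd.read_csv(indir / "cells.csv").sort_values("cell_id").reset_index(drop=True)
    cov_cols = [
        c for c in df.columns if c not in ("cell_id", "x", "y", "trials", "successes")
    ]
    X = np.column_stack([np.ones(grid.n_cells)] + [df[c].to_numpy(float) for c in cov_cols])
    return TrafficDataset(
        grid=grid,
        X=X,
        x_names=("intercept", *cov_cols),
        trials=df["trials"].to_numpy(np.int64),
        successes=df["successes"].to_numpy(np.int64),
    )


def read_observations(
    path: str | Path,
    x_col: str = "x",
    y_col: str = "y",
    label_col: str | None = None,
) -> pd.DataFrame:
    """Read a point-observation CSV with configurable column names."""
    df = pd.read_csv(path)
    for col in (x_col, y_col) + ((label_col,) if label_col else ()):
        if col not in df.columns:
            raise GridError(f"observation file {path} is missing column {col!r}")
    return df


def write_surface_csv(
    surface: PredictionSurface, grid: LatticeGrid, path: str | Path
) -> Path:
    """Per-cell CSV: cell_id, x, y, prob_median, prob_lower, prob_upper."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    centers = grid.cell_centers()
    pd.DataFrame(
        {
            "cell_id": grid.cell_ids,
            "x": centers[:, 0],
            "y": centers[:, 1],
            "prob_median": surface.prob_median,
            "prob_lower": surface.prob_lower,
            "prob_upper": surface.prob_upper,
        }
    ).to_csv(path, index=False, encoding="utf-8", float_format="%.10g")
    return path


def read_surface_csv(path: str | Path) -> PredictionSurface:
    df = pd.read_csv(path).sort_values("cell_id").reset_index(drop=True)
    return PredictionSurface(
        prob_median=df["prob_median"].to_numpy(float),
        prob_lower=df["prob_lower"].to_numpy(float),
        prob_upper=df["prob_upper"].to_numpy(float),
    )


def write_posterior(post, path: str | Path) -> Path:
    """Write retained draws as a named-column CSV (beta, gamma, V_rho, rho)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {f"beta[{n}]": post.beta_draws[:, j] for j, n in enumerate(post.x_names)}
    if post.gamma_draws is not None and post.w_names is not None:
        for j, n in enumerate(post.w_names):
            cols[f"gamma[{n}]"] = post.gamma_draws[:, j]
    cols["V_rho"] = post.vrho_draws
    for i in range(post.rho_draws.shape[1]):
        cols[f"rho[{i}]"] = post.rho_draws[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, encoding="utf-8", float_format="%.10g")
    return path


def read_posterior_draws(path: str | Path) -> dict[str, np.ndarray]:
    """Read a draws CSV back into arrays keyed 'beta', 'gamma', 'vrho', 'rho'."""
    df = pd.read_csv(path)
    beta_cols = [c for c in df.columns if c.startswith("beta[")]
    gamma_cols = [c for c in df.columns if c.startswith("gamma[")]
    rho_cols = sorted(
        (c for c in df.columns if c.startswith("rho[")),
        key=lambda c: int(c[4:-1]),
    )
    out = {
        "beta": df[beta_cols].to_numpy(float),
        "beta_names": tuple(c[5:-1] for c in beta_cols),
        "vrho": df["V_rho"].to_numpy(float),
        "rho": df[rho_cols].to_numpy(float),
    }
    if gamma_cols:
        out["gamma"] = df[gamma_cols].to_numpy(float)
        out["gamma_names"] = tuple(c[6:-1] for c in gamma_cols)
    return out


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
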