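"""Seeded generators for lattice datasets with known statistical structure.

Every generator is a pure function of its parameters and an integer seed:
calling twice with the same arguments returns identical output.  The
generated datasets have exactly the structure the samplers in
:mod:`spatocc.mcmc` assume — smooth standardized covariate fields, an
intrinsic CAR spatial effect, Bernoulli occupancy on the logit scale, and
repeat visits with imperfect detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from spatocc.grid import GridError, LatticeGrid, SiteDataset


class SimulationError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class SimulationTruth:
    """Ground-truth bundle for a simulated dataset.

    ``beta``/``gamma`` are logit-scale coefficient vectors including the
    intercept; ``rho`` sums to zero per connected component; ``z`` is the
    latent occupancy; ``pi``/``delta`` the cell- and visit-level
    probabilities actually used to draw the data.
    """

    beta: np.ndarray
    gamma: np.ndarray
    V_rho: float
    rho: np.ndarray
    z: np.ndarray
    pi: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int64)
        self.pi = np.asarray(self.pi, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if not (len(self.rho) == len(self.z) == len(self.pi)):
            raise SimulationError("rho, z and pi must share the cell dimension")
        if np.any((self.z != 0) & (self.z != 1)):
            raise SimulationError("z must be binary")
        # open interval (0, 1); the upper bound may saturate to 1.0 in floating
        # point under the perfect-detection limit (huge logit), which is allowed
        if np.any((self.pi <= 0) | (self.pi > 1)):
            raise SimulationError("pi must lie in (0, 1)")
        if self.delta.size and np.any((self.delta <= 0) | (self.delta > 1)):
            raise SimulationError("delta must lie in (0, 1)")


def simulate_covariate_field(
    grid: LatticeGrid, smoothness: float, seed: int
) -> np.ndarray:
    """Spatially autocorrelated standardized field on the lattice.

    White noise is smoothed with a Gaussian kernel of bandwidth
    ``smoothness`` (in cells) and then z-scored exactly, so the result has
    mean 0 and sd 1 to machine precision.  ``smoothness`` close to zero
    degenerates to an i.i.d. standard-normal field.
    """
    if smoothness <= 0:
        raise SimulationError(f"smoothness must be positive, got {smoothness}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((grid.n_rows, grid.n_cols))
    smooth = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    flat = smooth.ravel()
    sd = flat.std(ddof=0)
    if sd == 0:  # pragma: no cover - only for 1-cell grids
        return np.zeros(grid.n_cells)
    return (flat - flat.mean()) / sd


def simulate_icar_field(grid: LatticeGrid, V_rho: float, seed: int) -> np.ndarray:
    """Exact draw from the intrinsic CAR distribution on the lattice graph.

    Samples in the non-null eigenspace of the graph Laplacian ``L`` with
    per-direction variance ``V_rho / eigenvalue``, which realizes the
    singular Gaussian with covariance ``V_rho * pinv(L)``.  The sum-to-zero
    constraint holds per connected component by construction (the null
    space, spanned by component indicators, gets no mass).
    """
    if V_rho <= 0:
        raise SimulationError(f"V_rho must be positive, got {V_rho}")
    rng = np.random.default_rng(seed)
    lap = grid.laplacian().toarray()
    eigval, eigvec = np.linalg.eigh(lap)
    # eigenvalues at zero correspond to connected components: no variation there
    nonnull = eigval > 1e-10 * max(eigval.max(), 1.0)
    coefs = rng.standard_normal(int(nonnull.sum()))
    scale = np.sqrt(V_rho / eigval[nonnull])
    rho = eigvec[:, nonnull] @ (coefs * scale)
    # exact re-centering per component kills accumulated rounding
    _, labels = grid.components()
    for c in np.unique(labels):
        mask = labels == c
        rho[mask] -= rho[mask].mean()
    return rho


def _visit_plan(
    grid: LatticeGrid, visits_per_cell: int | np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell visit counts; default is right-skewed (mostly 1-2, few large)."""
    n = grid.n_cells
    if visits_per_cell is None:
        return 1 + rng.negative_binomial(1, 0.6, size=n)
    if np.isscalar(visits_per_cell):
        v = int(visits_per_cell)
        if v < 1:
            raise SimulationError("visits_per_cell must be >= 1")
        return np.full(n, v, dtype=np.int64)
    v = np.asarray(visits_per_cell, dtype=np.int64)
    if len(v) != n or np.any(v < 1):
        raise SimulationError("per-cell visit plan must have length n_cells and be >= 1")
    return v


def _conditions(
    n_visits: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated ordinal sea-state and wind covariates on a 0-4 scale."""
    latent = rng.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, 0.6], [0.6, 1.0]], size=n_visits
    )
    # skewed cutpoints: calm conditions dominate
    cuts = np.array([0.0, 0.85, 1.5, 2.1])
    sea = np.searchsorted(cuts, latent[:, 0])
    wind = np.searchsorted(cuts, latent[:, 1])
    return sea.astype(np.int64), wind.astype(np.int64)


def simulate_occupancy_dataset(
    grid: LatticeGrid,
    beta: np.ndarray,
    gamma: np.ndarray,
    V_rho: float = 0.0,
    visits_per_cell: int | np.ndarray | None = None,
    seed: int = 0,
    covariate_smoothness: float = 2.0,
    covariate_names: tuple[str, ...] | None = None,
    detection_terms: tuple[str, ...] | None = None,
) -> tuple[SiteDataset, SimulationTruth]:
    """Simulate a full site-occupancy survey dataset.

    Ecological process: ``logit(pi) = X @ beta + rho`` with ``z ~
    Bernoulli(pi)``; observation process: ``logit(delta) = W @ gamma`` with
    ``y ~ Bernoulli(z * delta)``.  ``X`` holds an intercept plus
    ``len(beta) - 1`` smooth standardized fields; ``W`` holds an intercept
    plus the ``detection_terms`` columns, drawn from ``effort`` (visit
    count), ``sea_state`` and ``wind``; by default the first
    ``len(gamma) - 1`` of those three.

    Set ``V_rho = 0`` for no spatial effect.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if len(gamma) < 1 or len(gamma) > 4:
        raise SimulationError("gamma must have 1-4 entries (intercept plus detection terms)")
    if detection_terms is None:
        detection_terms = ("effort", "sea_state", "wind")[: len(gamma) - 1]
    detection_terms = tuple(detection_terms)
    if len(detection_terms) != len(gamma) - 1:
        raise SimulationError("gamma must have one entry per detection term plus intercept")
    if any(t not in ("effort", "sea_state", "wind") for t in detection_terms):
        raise SimulationError("detection terms must be among effort, sea_state, wind")
    n_cov = len(beta) - 1
    if n_cov < 0:
        raise SimulationError("beta must at least contain an intercept")
    rng = np.random.default_rng(seed)
    sub = rng.spawn(5)

    fields = [
        simulate_covariate_field(grid, covariate_smoothness, int(s.integers(2**31)))
        for s in (sub[0].spawn(n_cov) if n_cov else [])
    ]
    X = np.column_stack([np.ones(grid.n_cells)] + fields) if fields else np.ones(
        (grid.n_cells, 1)
    )
    if covariate_names is None:
        covariate_names = tuple(f"cov{i+1}" for i in range(n_cov))
    if len(covariate_names) != n_cov:
        raise SimulationError("covariate_names length must match len(beta) - 1")
    x_names = ("intercept",) + tuple(covariate_names)

    if V_rho > 0:
        rho = simulate_icar_field(grid, V_rho, int(sub[1].integers(2**31)))
    else:
        rho = np.zeros(grid.n_cells)

    eta = X @ beta + rho
    pi = expit(eta)
    z = (sub[2].random(grid.n_cells) < pi).astype(np.int64)

    visits = _visit_plan(grid, visits_per_cell, sub[3])
    visit_cell = np.repeat(np.arange(grid.n_cells), visits)
    n_visits = len(visit_cell)
    sea, wind = _conditions(n_visits, sub[3])
    columns = {
        "effort": visits[visit_cell].astype(float),
        "sea_state": sea.astype(float),
        "wind": wind.astype(float),
    }
    W = np.column_stack([np.ones(n_visits)] + [columns[t] for t in detection_terms])
    w_names = ("intercept",) + detection_terms

    delta = expit(W @ gamma)
    y = ((sub[4].random(n_visits) < delta) & (z[visit_cell] == 1)).astype(np.int64)

    data = SiteDataset(
        grid=grid,
        X=X,
        x_names=x_names,
        W=W,
        w_names=w_names,
        y=y,
        visit_cell=visit_cell,
        visits=visits,
    )
    truth = SimulationTruth(
        beta=beta, gamma=gamma, V_rho=float(V_rho), rho=rho, z=z, pi=pi, delta=delta
    )
    return data, truth


@dataclass
class TrafficDataset:
    """Per-cell vessel presence/absence with covariates.

    ``trials``/``successes`` support the binomial model; for scan-level
    Bernoulli data trials are all one.
    """

    grid: LatticeGrid
    X: np.ndarray
    x_names: tuple[str, ...]
    trials: np.ndarray
    successes: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.trials = np.asarray(self.trials, dtype=np.int64)
        self.successes = np.asarray(self.successes, dtype=np.int64)
        if self.X.shape[0] != self.grid.n_cells:
            raise GridError("X rows must align with grid cells")
        if np.any(self.successes > self.trials) or np.any(self.successes < 0):
            raise GridError("successes must lie in [0, trials]")

    def design_for(self, term_names: tuple[str, ...]) -> np.ndarray:
        idx = [self.x_names.index("intercept")]
        for name in term_names:
            if name == "intercept":
                continue
            idx.append(self.x_names.index(name))
        return self.X[:, idx]


def simulate_traffic_dataset(
    grid: LatticeGrid,
    beta: np.ndarray,
    V_rho: float = 0.0,
    seed: int = 0,
    covariate_names: tuple[str, ...] = ("dist_coast",),
    covariate_smoothness: float = 2.0,
) -> tuple[TrafficDataset, SimulationTruth]:
    """Simulate per-cell vessel presence driven by distance-to-coast.

    The first covariate, ``dist_coast``, is deterministic: the standardized
    distance of each cell center from the western grid edge (a coastline
    stand-in).  Additional named covariates are smooth random fields.
    Presence is ``Bernoulli(logit^-1(X @ beta + rho))`` with one trial per
    cell.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if len(beta) != len(covariate_names) + 1:
        raise SimulationError("beta must have one entry per covariate plus intercept")
    rng = np.random.default_rng(seed)
    sub = rng.spawn(3)

    centers = grid.cell_centers()
    dist = centers[:, 0] - grid.origin[0]
    sd = dist.std(ddof=0)
    cols = [(dist - dist.mean()) / sd if sd > 0 else np.zeros_like(dist)]
    extra = sub[0].spawn(max(len(covariate_names) - 1, 0))
    for s in extra:
        cols.append(
            simulate_covariate_field(grid, covariate_smoothness, int(s.integers(2**31)))
        )
    X = np.column_stack([np.ones(grid.n_cells)] + cols)
    x_names = ("intercept",) + tuple(covariate_names)

    if V_rho > 0:
        rho = simulate_icar_field(grid, V_rho, int(sub[1].integers(2**31)))
    else:
        rho = np.zeros(grid.n_cells)

    pi = expit(X @ beta + rho)
    z = (sub[2].random(grid.n_cells) < pi).astype(np.int64)

    data = TrafficDataset(
        grid=grid,
        X=X,
        x_names=x_names,
        trials=np.ones(grid.n_cells, dtype=np.int64),
        successes=z,
    )
    truth = SimulationTruth(
        beta=beta,
        gamma=np.empty(0),
        V_rho=float(V_rho),
        rho=rho,
        z=z,
        pi=pi,
        delta=np.empty(0),
    )
    return data, truth
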