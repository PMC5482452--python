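"""Metropolis-within-Gibbs samplers for lattice occupancy models.

Two models share the machinery:

* a site-occupancy model with imperfect detection — latent occupancy
  ``z_i ~ Bernoulli(pi_i)`` with ``logit(pi_i) = x_i' beta + rho_i``, and
  per-visit detections ``y_it ~ Bernoulli(z_i * delta_it)`` with
  ``logit(delta_it) = w_it' gamma``;
* a binomial model — ``s_i ~ Binomial(t_i, pi_i)`` with the same
  logit-linear spatial predictor and no observation layer.

``rho`` carries an intrinsic CAR prior: conditionally normal around the
mean of its lattice neighbors with variance ``V_rho / n_i``, identified by
re-centering to zero mean per connected component every sweep.  Priors are
Normal(0, 100) on all coefficients and Uniform on ``V_rho``.

Updates are adaptive scalar random-walk Metropolis for ``beta``, ``gamma``
and ``V_rho`` (the latter on the log scale with prior-bound rejection),
Gibbs for the latent ``z``, and blocked random-walk Metropolis for ``rho``
using a graph coloring so that non-adjacent cells update simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from spatocc.grid import GridError, LatticeGrid, SiteDataset
from spatocc.synthetic import TrafficDataset

logger = logging.getLogger(__name__)

RHAT_WARN = 1.1


class ModelError(ValueError):
    """Invalid model specification or degenerate data."""


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the two linear predictors, and the priors.

    ``ecological_terms`` name columns of the per-cell design matrix (the
    intercept is always included and need not be listed); ``detection_terms``
    likewise for the visit-level matrix and are empty for the binomial
    model.  ``interactions`` are pairs of ecological terms whose product
    (re-standardized) is appended to the design.
    """

    ecological_terms: tuple[str, ...] = ()
    detection_terms: tuple[str, ...] = ()
    prior_coef_variance: float = 100.0
    prior_vrho_bounds: tuple[float, float] = (0.0, 10.0)
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.prior_coef_variance <= 0:
            raise ModelError("prior_coef_variance must be positive")
        a, b = self.prior_vrho_bounds
        if not (0 <= a < b):
            raise ModelError("V_rho prior bounds must satisfy 0 <= a < b")
        for pair in self.interactions:
            if len(pair) != 2:
                raise ModelError("interactions must be pairs of term names")
            if pair[0] not in self.ecological_terms or pair[1] not in self.ecological_terms:
                raise ModelError(
                    f"interaction {pair!r} requires both main effects in ecological_terms"
                )

    @property
    def n_terms(self) -> int:
        return len(self.ecological_terms) + len(self.interactions) + len(self.detection_terms)

    def term_label(self) -> str:
        mains = "+".join(self.ecological_terms) or "1"
        inter = "+".join(f"{a}:{b}" for a, b in self.interactions)
        return mains + (f"+{inter}" if inter else "")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout and adaptation settings."""

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    n_chains: int = 2
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ModelError("n_iter must exceed burn_in")
        if self.thin < 1 or self.n_chains < 1:
            raise ModelError("thin and n_chains must be >= 1")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (chains concatenated) plus diagnostics."""

    beta_draws: np.ndarray  # (draws, p)
    gamma_draws: np.ndarray | None  # (draws, q) or None for binomial model
    rho_draws: np.ndarray  # (draws, n_cells)
    vrho_draws: np.ndarray  # (draws,)
    z_draws: np.ndarray | None  # (draws, n_cells) or None
    acceptance_rates: dict[str, float]
    mcmc_config: MCMCConfig
    spec: ModelSpec
    x_names: tuple[str, ...]
    w_names: tuple[str, ...] | None = None
    rhat: dict[str, float] = field(default_factory=dict)
    chain_lengths: tuple[int, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def beta_summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for j, name in enumerate(self.x_names):
            d = self.beta_draws[:, j]
            out[name] = {
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "q2.5": float(np.quantile(d, 0.025)),
                "q97.5": float(np.quantile(d, 0.975)),
            }
        return out


@dataclass
class PredictionSurface:
    """Per-cell posterior summary of the presence probability."""

    prob_median: np.ndarray
    prob_lower: np.ndarray  # 2.5% quantile
    prob_upper: np.ndarray  # 97.5% quantile
    grid: LatticeGrid | None = None
    rho_included: bool = True

    def __post_init__(self) -> None:
        for arr in (self.prob_median, self.prob_lower, self.prob_upper):
            if np.any((arr < 0) | (arr > 1)):
                raise ModelError("probabilities must lie in [0, 1]")


def _standardize_column(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    if sd == 0:
        raise ModelError("interaction column has zero variance")
    return (col - col.mean()) / sd


def ecological_design(
    data: SiteDataset | TrafficDataset, spec: ModelSpec
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Assemble the per-cell design matrix for ``spec`` (intercept first)."""
    X = data.design_for(spec.ecological_terms)
    names = ["intercept", *spec.ecological_terms]
    cols = [X]
    for a, b in spec.interactions:
        ia = data.x_names.index(a)
        ib = data.x_names.index(b)
        cols.append(_standardize_column(data.X[:, ia] * data.X[:, ib])[:, None])
        names.append(f"{a}:{b}")
    return np.hstack(cols), tuple(names)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _greedy_coloring(n: int, adjacency: np.ndarray) -> list[np.ndarray]:
    """Partition cells into independent sets (no two same-color cells adjacent)."""
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in adjacency:
        neighbors[i].append(j)
        neighbors[j].append(i)
    color = -np.ones(n, dtype=np.int64)
    for v in range(n):
        used = {color[u] for u in neighbors[v] if color[u] >= 0}
        c = 0
        while c in used:
            c += 1
        color[v] = c
    return [np.flatnonzero(color == c) for c in range(color.max() + 1)]


class _SpatialState:
    """Shared iCAR structure: adjacency, coloring, components."""

    def __init__(self, grid: LatticeGrid, vrho_bounds: tuple[float, float]):
        self.n = grid.n_cells
        self.adj = grid.adjacency
        self.A = grid.adjacency_matrix()
        self.n_neighbors = grid.neighbor_counts().astype(float)
        n_comp, labels = grid.components()
        self.labels = labels
        # singleton cells (no neighbors) keep rho = 0
        self.active = self.n_neighbors > 0
        comp_sizes = np.bincount(labels)
        self.rank = int(np.sum(np.maximum(comp_sizes - 1, 0)))
        self.colors = [
            c[self.active[c]] for c in _greedy_coloring(self.n, self.adj)
        ]
        self.colors = [c for c in self.colors if c.size]
        self.A_by_color = [self.A[c] for c in self.colors]
        self.vrho_bounds = vrho_bounds
        # component index lists for recentring (non-singleton only)
        self.comp_cells = [
            np.flatnonzero(labels == k) for k in range(n_comp) if comp_sizes[k] > 1
        ]

    def recenter(self, rho: np.ndarray) -> None:
        for cells in self.comp_cells:
            rho[cells] -= rho[cells].mean()

    def pairwise_ss(self, rho: np.ndarray) -> float:
        if not self.adj.size:
            return 0.0
        d = rho[self.adj[:, 0]] - rho[self.adj[:, 1]]
        return float(d @ d)


def _bern_loglik(eta: np.ndarray, s: np.ndarray, f: np.ndarray) -> float:
    """sum s*log(expit(eta)) + f*log(1-expit(eta)); s/f are success/failure counts."""
    return float(s @ log_expit(eta) + f @ log_expit(-eta))


class _Adaptive:
    """Per-scalar random-walk scale adapted toward a target acceptance rate."""

    def __init__(self, n: int, interval: int, target: float):
        self.log_scale = np.zeros(n)
        self.accept = np.zeros(n)
        self.tries = np.zeros(n)
        self.interval = interval
        self.target = target
        self.total_accept = np.zeros(n)
        self.total_tries = np.zeros(n)

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def record(self, accepted: np.ndarray, idx=slice(None)) -> None:
        self.accept[idx] += accepted
        self.tries[idx] += 1
        self.total_accept[idx] += accepted
        self.total_tries[idx] += 1

    def maybe_adapt(self, iteration: int, adapting: bool) -> None:
        if not adapting or iteration == 0 or iteration % self.interval:
            return
        rate = np.where(self.tries > 0, self.accept / np.maximum(self.tries, 1), self.target)
        self.log_scale += (rate - self.target)
        np.clip(self.log_scale, -8.0, 5.0, out=self.log_scale)
        self.accept[:] = 0
        self.tries[:] = 0

    def overall_rate(self) -> float:
        tot = self.total_tries.sum()
        return float(self.total_accept.sum() / tot) if tot else float("nan")


def _update_coefs(
    coefs: np.ndarray,
    eta: np.ndarray,
    design: np.ndarray,
    s: np.ndarray,
    f: np.ndarray,
    prior_var: float,
    adapt: _Adaptive,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scalar RW-Metropolis sweep over a coefficient vector; returns updated eta."""
    scales = adapt.scale
    for j in range(len(coefs)):
        step = scales[j] * rng.standard_normal()
        prop = coefs[j] + step
        eta_prop = eta + step * design[:, j]
        log_r = (
            _bern_loglik(eta_prop, s, f)
            - _bern_loglik(eta, s, f)
            + (coefs[j] ** 2 - prop**2) / (2 * prior_var)
        )
        if np.log(rng.random()) < log_r:
            coefs[j] = prop
            eta = eta_prop
            adapt.record(1.0, j)
        else:
            adapt.record(0.0, j)
    return eta


def _update_rho(
    rho: np.ndarray,
    eta_fixed: np.ndarray,
    s: np.ndarray,
    f: np.ndarray,
    V: float,
    sp: _SpatialState,
    adapt: _Adaptive,
    rng: np.random.Generator,
) -> None:
    """Blocked RW-Metropolis on rho by graph color (in place)."""
    for cells, A_sub in zip(sp.colors, sp.A_by_color):
        neigh_sum = A_sub @ rho
        ni = sp.n_neighbors[cells]
        m = neigh_sum / ni
        cur = rho[cells]
        prop = cur + adapt.scale[cells] * rng.standard_normal(len(cells))
        eta_cur = eta_fixed[cells] + cur
        eta_prop = eta_fixed[cells] + prop
        ll_delta = (
            s[cells] * (log_expit(eta_prop) - log_expit(eta_cur))
            + f[cells] * (log_expit(-eta_prop) - log_expit(-eta_cur))
        )
        # V can adapt arbitrarily close to 0 under collapsed prior bounds;
        # the floor only pins rho harder, never loosens it
        prior_delta = (ni / (2 * max(V, 1e-12))) * ((cur - m) ** 2 - (prop - m) ** 2)
        accepted = np.log(rng.random(len(cells))) < ll_delta + prior_delta
        rho[cells[accepted]] = prop[accepted]
        adapt.record(accepted.astype(float), cells)


def _update_vrho(
    V: float,
    rho: np.ndarray,
    sp: _SpatialState,
    adapt: _Adaptive,
    rng: np.random.Generator,
) -> float:
    """RW-Metropolis on log V_rho with uniform-prior bound rejection.

    A numerical floor of 1e-12 prevents underflow when the prior is
    deliberately collapsed toward zero.
    """
    a, b = sp.vrho_bounds
    ss = sp.pairwise_ss(rho)

    def log_target(v: float) -> float:
        return -0.5 * sp.rank * np.log(v) - ss / (2 * v)

    prop = float(np.exp(np.log(V) + adapt.scale[0] * rng.standard_normal()))
    if prop <= max(a, 1e-12) or prop >= b:
        adapt.record(np.array([0.0]))
        return V
    log_r = log_target(prop) - log_target(V) + (np.log(prop) - np.log(V))
    if np.log(rng.random()) < log_r:
        adapt.record(np.array([1.0]))
        return prop
    adapt.record(np.array([0.0]))
    return V


def _split_rhat(chains: list[np.ndarray]) -> float:
    """Gelman-Rubin potential scale reduction on split chains."""
    halves = []
    for c in chains:
        h = len(c) // 2
        if h >= 2:
            halves.extend([c[:h], c[h : 2 * h]])
    if len(halves) < 2:
        return float("nan")
    m = len(halves)
    n = min(len(h) for h in halves)
    arr = np.array([h[:n] for h in halves])
    means = arr.mean(axis=1)
    variances = arr.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# site-occupancy model
# ---------------------------------------------------------------------------


def fit_site_occupancy_icar(
    data: SiteDataset,
    spec: ModelSpec,
    mcmc: MCMCConfig | None = None,
    fixed_gamma: np.ndarray | None = None,
) -> PosteriorSamples:
    """Posterior draws for the site-occupancy iCAR model.

    The latent occupancy ``z`` is Gibbs-sampled from its full conditional:
    cells with at least one detection are fixed at ``z = 1``; for the rest
    ``P(z=1 | ...) = pi * q / (pi * q + 1 - pi)`` with ``q`` the probability
    of missing the species on every visit (1 for unvisited cells, which are
    thereby excluded from the detection likelihood but retained for
    prediction).

    ``fixed_gamma`` holds the detection coefficients constant instead of
    sampling them (e.g. a huge intercept forces perfect detection).
    """
    mcmc = mcmc or MCMCConfig()
    if data.n_visits == 0:
        raise ModelError("no visits: the detection likelihood is empty")
    Xs, x_names = ecological_design(data, spec)
    W = data.detection_design_for(spec.detection_terms)
    w_names = ("intercept", *spec.detection_terms)
    if fixed_gamma is not None:
        fixed_gamma = np.atleast_1d(np.asarray(fixed_gamma, dtype=float))
        if len(fixed_gamma) != W.shape[1]:
            raise ModelError("fixed_gamma length must match detection design columns")
    detected = data.any_detection()
    visited = data.visits > 0
    if not visited.any():
        raise ModelError("no visited cells")
    if np.all(detected[visited] == 1):
        raise ModelError(
            "degenerate data: every visited cell has a detection; "
            "the occupancy layer is not identifiable"
        )
    n = data.n_cells
    p = Xs.shape[1]
    q = W.shape[1]
    sp = _SpatialState(data.grid, spec.prior_vrho_bounds)
    vc = data.visit_cell
    y = data.y.astype(float)

    keep_per_chain = (mcmc.n_iter - mcmc.burn_in) // mcmc.thin
    chains_beta, chains_gamma, chains_rho = [], [], []
    chains_v, chains_z = [], []
    acc_report: dict[str, list[float]] = {"beta": [], "gamma": [], "rho": [], "vrho": []}

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([mcmc.seed, chain])
        beta = np.zeros(p)
        gamma = fixed_gamma.copy() if fixed_gamma is not None else np.zeros(q)
        rho = np.zeros(n)
        a, b = spec.prior_vrho_bounds
        V = min(max(1.0, a + 1e-3 * (b - a)), 0.5 * (a + b))
        z = detected.astype(float)

        ad_beta = _Adaptive(p, mcmc.adapt_interval, mcmc.target_accept)
        ad_gamma = _Adaptive(q, mcmc.adapt_interval, mcmc.target_accept)
        ad_rho = _Adaptive(n, mcmc.adapt_interval, mcmc.target_accept)
        ad_v = _Adaptive(1, mcmc.adapt_interval, mcmc.target_accept)

        xb = Xs @ beta
        eta = xb + rho
        eta_det = W @ gamma

        out_beta = np.empty((keep_per_chain, p))
        out_gamma = np.empty((keep_per_chain, q))
        out_rho = np.empty((keep_per_chain, n))
        out_v = np.empty(keep_per_chain)
        out_z = np.empty((keep_per_chain, n), dtype=np.int8)
        k = 0

        for it in range(mcmc.n_iter):
            adapting = it < mcmc.burn_in

            # --- Gibbs z: logit P(z=1) = logit(pi) + log q(miss all visits)
            log_miss = np.bincount(vc, weights=log_expit(-eta_det), minlength=n)
            p_z1 = expit(eta + log_miss)
            z = (rng.random(n) < p_z1).astype(float)
            z[detected == 1] = 1.0

            s_cell = z
            f_cell = 1.0 - z

            # --- beta
            eta = _update_coefs(
                beta, eta, Xs, s_cell, f_cell, spec.prior_coef_variance, ad_beta, rng
            )

            # --- gamma (visits at occupied cells only)
            if fixed_gamma is None:
                zv = z[vc]
                s_vis = zv * y
                f_vis = zv * (1.0 - y)
                eta_det = _update_coefs(
                    gamma, eta_det, W, s_vis, f_vis, spec.prior_coef_variance,
                    ad_gamma, rng,
                )

            # --- rho
            xb = eta - rho
            _update_rho(rho, xb, s_cell, f_cell, V, sp, ad_rho, rng)
            sp.recenter(rho)
            eta = xb + rho

            # --- V_rho
            V = _update_vrho(V, rho, sp, ad_v, rng)

            for ad in (ad_beta, ad_gamma, ad_rho, ad_v):
                ad.maybe_adapt(it + 1, adapting)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and k < keep_per_chain:
                out_beta[k] = beta
                out_gamma[k] = gamma
                out_rho[k] = rho
                out_v[k] = V
                out_z[k] = z
                k += 1

        chains_beta.append(out_beta[:k])
        chains_gamma.append(out_gamma[:k])
        chains_rho.append(out_rho[:k])
        chains_v.append(out_v[:k])
        chains_z.append(out_z[:k])
        acc_report["beta"].append(ad_beta.overall_rate())
        acc_report["gamma"].append(ad_gamma.overall_rate())
        acc_report["rho"].append(ad_rho.overall_rate())
        acc_report["vrho"].append(ad_v.overall_rate())

    rhat = _coef_rhat(chains_beta, x_names, chains_v)
    post = PosteriorSamples(
        beta_draws=np.vstack(chains_beta),
        gamma_draws=np.vstack(chains_gamma),
        rho_draws=np.vstack(chains_rho),
        vrho_draws=np.concatenate(chains_v),
        z_draws=np.vstack(chains_z),
        acceptance_rates={
            k: (float(np.nanmean(v)) if np.any(np.isfinite(v)) else float("nan"))
            for k, v in acc_report.items()
        },
        mcmc_config=mcmc,
        spec=spec,
        x_names=x_names,
        w_names=w_names,
        rhat=rhat,
        chain_lengths=tuple(len(c) for c in chains_beta),
    )
    _warn_rhat(post)
    return post


# ---------------------------------------------------------------------------
# binomial model
# ---------------------------------------------------------------------------


def fit_binomial_icar(
    data: TrafficDataset,
    spec: ModelSpec,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Posterior draws for the binomial iCAR model (no detection layer).

    Cells with zero trials contribute only through the spatial prior and
    are retained for prediction.
    """
    mcmc = mcmc or MCMCConfig()
    if spec.detection_terms:
        raise ModelError("the binomial model has no detection terms")
    if np.any(data.successes > data.trials):
        raise ModelError("successes exceed trials")
    Xs, x_names = ecological_design(data, spec)
    n = data.grid.n_cells
    p = Xs.shape[1]
    sp = _SpatialState(data.grid, spec.prior_vrho_bounds)
    s_cell = data.successes.astype(float)
    f_cell = (data.trials - data.successes).astype(float)

    keep_per_chain = (mcmc.n_iter - mcmc.burn_in) // mcmc.thin
    chains_beta, chains_rho, chains_v = [], [], []
    acc_report: dict[str, list[float]] = {"beta": [], "rho": [], "vrho": []}

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([mcmc.seed, chain])
        beta = np.zeros(p)
        rho = np.zeros(n)
        a, b = spec.prior_vrho_bounds
        V = min(max(1.0, a + 1e-3 * (b - a)), 0.5 * (a + b))

        ad_beta = _Adaptive(p, mcmc.adapt_interval, mcmc.target_accept)
        ad_rho = _Adaptive(n, mcmc.adapt_interval, mcmc.target_accept)
        ad_v = _Adaptive(1, mcmc.adapt_interval, mcmc.target_accept)

        eta = Xs @ beta + rho

        out_beta = np.empty((keep_per_chain, p))
        out_rho = np.empty((keep_per_chain, n))
        out_v = np.empty(keep_per_chain)
        k = 0

        for it in range(mcmc.n_iter):
            adapting = it < mcmc.burn_in
            eta = _update_coefs(
                beta, eta, Xs, s_cell, f_cell, spec.prior_coef_variance, ad_beta, rng
            )
            xb = eta - rho
            _update_rho(rho, xb, s_cell, f_cell, V, sp, ad_rho, rng)
            sp.recenter(rho)
            eta = xb + rho
            V = _update_vrho(V, rho, sp, ad_v, rng)
            for ad in (ad_beta, ad_rho, ad_v):
                ad.maybe_adapt(it + 1, adapting)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and k < keep_per_chain:
                out_beta[k] = beta
                out_rho[k] = rho
                out_v[k] = V
                k += 1

        chains_beta.append(out_beta[:k])
        chains_rho.append(out_rho[:k])
        chains_v.append(out_v[:k])
        acc_report["beta"].append(ad_beta.overall_rate())
        acc_report["rho"].append(ad_rho.overall_rate())
        acc_report["vrho"].append(ad_v.overall_rate())

    rhat = _coef_rhat(chains_beta, x_names, chains_v)
    post = PosteriorSamples(
        beta_draws=np.vstack(chains_beta),
        gamma_draws=None,
        rho_draws=np.vstack(chains_rho),
        vrho_draws=np.concatenate(chains_v),
        z_draws=None,
        acceptance_rates={
            k: (float(np.nanmean(v)) if np.any(np.isfinite(v)) else float("nan"))
            for k, v in acc_report.items()
        },
        mcmc_config=mcmc,
        spec=spec,
        x_names=x_names,
        w_names=None,
        rhat=rhat,
        chain_lengths=tuple(len(c) for c in chains_beta),
    )
    _warn_rhat(post)
    return post


def _coef_rhat(
    chains_beta: list[np.ndarray],
    x_names: tuple[str, ...],
    chains_v: list[np.ndarray],
) -> dict[str, float]:
    rhat = {}
    for j, name in enumerate(x_names):
        rhat[f"beta[{name}]"] = _split_rhat([c[:, j] for c in chains_beta])
    rhat["V_rho"] = _split_rhat(chains_v)
    return rhat


def _warn_rhat(post: PosteriorSamples) -> None:
    for name, value in post.rhat.items():
        if np.isfinite(value) and value > RHAT_WARN:
            logger.warning("R-hat %.3f > %.1f for %s", value, RHAT_WARN, name)


# ---------------------------------------------------------------------------
# prediction and DIC
# ---------------------------------------------------------------------------


def predict_surface(
    post: PosteriorSamples,
    X_new: np.ndarray,
    x_names: tuple[str, ...] | None = None,
    grid: LatticeGrid | None = None,
    use_rho: bool = True,
) -> PredictionSurface:
    """Posterior median and 95% band of the presence probability.

    ``X_new`` columns must match the fitted design (checked against
    ``x_names`` when given).  When ``X_new`` has one row per fitted cell
    and ``use_rho`` is true, each cell's own ``rho`` draws enter the linear
    predictor; otherwise ``rho = 0`` is used and the surface is flagged
    (``rho_included=False``).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != post.beta_draws.shape[1]:
        raise ModelError(
            f"X_new must have {post.beta_draws.shape[1]} columns matching the fit"
        )
    if x_names is not None and tuple(x_names) != tuple(post.x_names):
        raise ModelError(f"column names {x_names!r} do not match fit {post.x_names!r}")
    eta = post.beta_draws @ X_new.T  # (draws, cells)
    rho_ok = use_rho and X_new.shape[0] == post.rho_draws.shape[1]
    if rho_ok:
        eta = eta + post.rho_draws
    elif use_rho:
        logger.info("rho draws unavailable for these cells; predicting with rho=0")
    prob = expit(eta)
    return PredictionSurface(
        prob_median=np.median(prob, axis=0),
        prob_lower=np.quantile(prob, 0.025, axis=0),
        prob_upper=np.quantile(prob, 0.975, axis=0),
        grid=grid,
        rho_included=bool(rho_ok),
    )


def observable_presence_prob(
    post: PosteriorSamples,
    X_new: np.ndarray,
    W_new: np.ndarray,
    visit_cell: np.ndarray,
    n_cells: int,
) -> np.ndarray:
    """Posterior mean of P(detect at least once) = pi * (1 - prod_t(1 - delta_t)).

    ``W_new``/``visit_cell`` describe the planned visits of the ``n_cells``
    cells scored; cells with no planned visits get probability 0.  ``rho``
    is taken as 0 (held-out cells).
    """
    if post.gamma_draws is None:
        raise ModelError("observable presence requires a detection layer")
    eta = post.beta_draws @ np.asarray(X_new, dtype=float).T
    pi = expit(eta)  # (draws, cells)
    log_miss_vis = log_expit(-(post.gamma_draws @ np.asarray(W_new, dtype=float).T))
    log_miss = np.vstack(
        [np.bincount(visit_cell, weights=row, minlength=n_cells) for row in log_miss_vis]
    )
    p_obs = pi * (1.0 - np.exp(log_miss))
    return p_obs.mean(axis=0)


def _occupancy_cell_loglik(
    pi: np.ndarray, log_det: np.ndarray, visit_cell: np.ndarray, detected: np.ndarray,
    visited: np.ndarray,
) -> float:
    """z-marginalized log-likelihood summed over visited cells.

    ``log_det`` are per-visit log Bernoulli terms log[delta^y (1-delta)^(1-y)].
    For detected cells L_i = pi_i * prod_t(...); otherwise
    L_i = pi_i * prod_t(1 - delta_it) + (1 - pi_i).
    """
    n = len(pi)
    cell_logdet = np.bincount(visit_cell, weights=log_det, minlength=n)
    ll = 0.0
    det = detected & visited
    miss = (~detected) & visited
    ll += np.sum(np.log(pi[det]) + cell_logdet[det])
    ll += np.sum(np.log(pi[miss] * np.exp(cell_logdet[miss]) + (1.0 - pi[miss])))
    return float(ll)


def compute_dic(
    post: PosteriorSamples, data: SiteDataset | TrafficDataset
) -> tuple[float, float, float]:
    """Deviance Information Criterion ``(DIC, Dbar, pD)``.

    ``Dbar`` is the posterior mean deviance, ``pD = Dbar - D(theta_bar)``
    with ``theta_bar`` the posterior means of the continuous parameters
    (beta, gamma, rho).  For the occupancy model the deviance marginalizes
    the latent ``z`` per cell so that ``pD`` is stable.
    """
    if post.n_draws == 0:
        raise ModelError("empty posterior")
    if isinstance(data, SiteDataset):
        Xs, _ = ecological_design(data, post.spec)
        W = data.detection_design_for(post.spec.detection_terms)
        detected = data.any_detection().astype(bool)
        visited = data.visits > 0
        vc = data.visit_cell
        y = data.y.astype(float)

        def deviance(beta, gamma, rho):
            pi = expit(Xs @ beta + rho)
            eta_d = W @ gamma
            log_det = y * log_expit(eta_d) + (1.0 - y) * log_expit(-eta_d)
            return -2.0 * _occupancy_cell_loglik(pi, log_det, vc, detected, visited)

        devs = np.array(
            [
                deviance(post.beta_draws[m], post.gamma_draws[m], post.rho_draws[m])
                for m in range(post.n_draws)
            ]
        )
        d_hat = deviance(
            post.beta_draws.mean(axis=0),
            post.gamma_draws.mean(axis=0),
            post.rho_draws.mean(axis=0),
        )
    else:
        Xs, _ = ecological_design(data, post.spec)
        s = data.successes.astype(float)
        f = (data.trials - data.successes).astype(float)

        def deviance_b(beta, rho):
            eta = Xs @ beta + rho
            return -2.0 * _bern_loglik(eta, s, f)

        devs = np.array(
            [deviance_b(post.beta_draws[m], post.rho_draws[m]) for m in range(post.n_draws)]
        )
        d_hat = deviance_b(post.beta_draws.mean(axis=0), post.rho_draws.mean(axis=0))
    dbar = float(devs.mean())
    pd = dbar - float(d_hat)
    return dbar + pd, dbar, pd
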