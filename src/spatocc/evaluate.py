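"""Model selection and predictive evaluation.

Candidate models are all non-empty subsets of the main effects (plus
hierarchy-respecting interaction variants), ranked by DIC.  Predictive skill
is measured by AUC (Mann-Whitney with tie correction) and the True Skill
Statistic, under repeated random 75/25 train/test splits at the cell level.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from spatocc.grid import SiteDataset
from spatocc.mcmc import (
    MCMCConfig,
    ModelSpec,
    compute_dic,
    fit_site_occupancy_icar,
    observable_presence_prob,
)

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Invalid evaluation input."""


# ---------------------------------------------------------------------------
# candidate enumeration and selection
# ---------------------------------------------------------------------------


def enumerate_candidates(
    covariates: list[str],
    max_interactions: int = 0,
    cap: int = 1024,
    include_intercept_only: bool = False,
    allow_truncation: bool = True,
    detection_terms: tuple[str, ...] = (),
    prior_vrho_bounds: tuple[float, float] = (0.0, 10.0),
) -> list[ModelSpec]:
    """All covariate-subset models, optionally with pairwise interactions.

    The intercept is always included.  Interaction terms are only attached
    to candidates containing both main effects (hierarchy), at most
    ``max_interactions`` per candidate.  The list is truncated at ``cap``
    with a warning when ``allow_truncation``; otherwise exceeding the cap
    raises.
    """
    if cap < 1:
        raise EvaluationError("cap must be >= 1")
    names = list(covariates)
    specs: list[ModelSpec] = []
    if include_intercept_only:
        specs.append(
            ModelSpec(
                ecological_terms=(),
                detection_terms=detection_terms,
                prior_vrho_bounds=prior_vrho_bounds,
            )
        )
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            pairs = list(itertools.combinations(subset, 2))
            inter_variants: list[tuple[tuple[str, str], ...]] = [()]
            if max_interactions > 0:
                for k in range(1, min(max_interactions, len(pairs)) + 1):
                    inter_variants.extend(itertools.combinations(pairs, k))
            for inter in inter_variants:
                specs.append(
                    ModelSpec(
                        ecological_terms=subset,
                        detection_terms=detection_terms,
                        interactions=inter,
                        prior_vrho_bounds=prior_vrho_bounds,
                    )
                )
    if len(specs) > cap:
        if not allow_truncation:
            raise EvaluationError(
                f"{len(specs)} candidates exceed cap={cap} and truncation is disabled"
            )
        warnings.warn(
            f"truncating candidate list from {len(specs)} to cap={cap}", stacklevel=2
        )
        specs = specs[:cap]
    return specs


def select_model(fits: list[tuple[ModelSpec, float]]) -> ModelSpec:
    """Lowest-DIC candidate; ties broken toward fewer terms, then term order."""
    if not fits:
        raise EvaluationError("no fitted candidates to select from")
    return min(
        fits,
        key=lambda sf: (sf[1], sf[0].n_terms, sf[0].term_label()),
    )[0]


# ---------------------------------------------------------------------------
# scoring metrics
# ---------------------------------------------------------------------------


def _check_two_classes(labels: np.ndarray) -> None:
    if not np.any(labels == 1):
        raise EvaluationError("no positive labels present")
    if not np.any(labels == 0):
        raise EvaluationError("no negative labels present")


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with ties counting 1/2."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores must have equal length")
    _check_two_classes(labels)
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold_rule: str = "max_sens_spec",
    threshold: float | None = None,
) -> tuple[float, float]:
    """True Skill Statistic = sensitivity + specificity - 1.

    Predicted positive when ``score >= threshold``.  Under the default
    ``max_sens_spec`` rule the threshold maximizing sensitivity +
    specificity over the observed score cut-points is used; ``fixed``
    requires an explicit ``threshold``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    if threshold_rule == "fixed":
        if threshold is None:
            raise EvaluationError("fixed threshold rule requires a threshold")
        return _tss_at(labels, scores, threshold), float(threshold)
    if threshold_rule != "max_sens_spec":
        raise EvaluationError(f"unknown threshold rule {threshold_rule!r}")
    best_tss, best_thr = -np.inf, np.nan
    for thr in np.unique(scores):
        t = _tss_at(labels, scores, thr)
        if t > best_tss:
            best_tss, best_thr = t, thr
    return float(best_tss), float(best_thr)


def _tss_at(labels: np.ndarray, scores: np.ndarray, thr: float) -> float:
    pred = scores >= thr
    pos = labels == 1
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens + spec - 1.0


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-repeat and mean predictive skill under random 75/25 splits."""

    auc_per_repeat: list[float]
    tss_per_repeat: list[float]
    thresholds: list[float]
    splits: list[dict] = field(default_factory=list)
    n_resampled: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_repeat))

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.tss_per_repeat))

    def to_dict(self) -> dict:
        return {
            "auc_per_repeat": self.auc_per_repeat,
            "tss_per_repeat": self.tss_per_repeat,
            "thresholds": self.thresholds,
            "mean_auc": self.mean_auc,
            "mean_tss": self.mean_tss,
            "splits": self.splits,
            "n_resampled": self.n_resampled,
        }


def cross_validate(
    data: SiteDataset,
    spec: ModelSpec,
    repeats: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    max_resamples: int = 20,
) -> CVResult:
    """Repeated random-split validation of the occupancy model.

    Each repeat draws a random ``train_frac``/``1 - train_frac`` partition
    of the *visited* cells (cell-level split: visits travel with their
    cell), refits on the training cells and scores the held-out cells'
    any-detection indicator against the predicted observable-presence
    probability ``pi * (1 - prod_t (1 - delta_t))`` under each held-out
    cell's own visit plan (``rho = 0`` for held-out cells).  Splits with a
    one-class training or test side are redrawn, with a log entry.
    """
    if not 0 < train_frac < 1:
        raise EvaluationError("train_frac must be in (0, 1)")
    mcmc = mcmc or MCMCConfig(n_iter=3000, burn_in=1500, thin=3, n_chains=1)
    visited = np.flatnonzero(data.visits > 0)
    detected = data.any_detection()
    if len(visited) < 8:
        raise EvaluationError("too few visited cells to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * len(visited)))
    n_train = min(max(n_train, 1), len(visited) - 1)

    aucs, tsss, thrs, splits = [], [], [], []
    n_resampled = 0
    for rep in range(repeats):
        for attempt in range(max_resamples):
            perm = rng.permutation(visited)
            train_cells, test_cells = perm[:n_train], perm[n_train:]
            lab_train = detected[train_cells]
            lab_test = detected[test_cells]
            if 0 < lab_train.sum() < len(lab_train) and 0 < lab_test.sum() < len(lab_test):
                break
            n_resampled += 1
            logger.info("repeat %d: one-class split, resampling (%d)", rep, attempt + 1)
        else:
            raise EvaluationError(
                f"repeat {rep}: could not draw a two-class split in {max_resamples} tries"
            )
        train_data, _ = data.subset_cells(train_cells)
        post = fit_site_occupancy_icar(train_data, spec, mcmc)

        # held-out design + visit plan, remapped to consecutive test ids
        from spatocc.mcmc import ecological_design

        X_all, _ = ecological_design(data, spec)
        W_all = data.detection_design_for(spec.detection_terms)
        new_id = -np.ones(data.n_cells, dtype=np.int64)
        new_id[test_cells] = np.arange(len(test_cells))
        vmask = new_id[data.visit_cell] >= 0
        scores = observable_presence_prob(
            post,
            X_all[test_cells],
            W_all[vmask],
            new_id[data.visit_cell[vmask]],
            len(test_cells),
        )
        a = auc(lab_test, scores)
        t, thr = tss(lab_test, scores)
        aucs.append(a)
        tsss.append(t)
        thrs.append(thr)
        splits.append(
            {
                "repeat": rep,
                "train_cells": [int(c) for c in train_cells],
                "test_cells": [int(c) for c in test_cells],
            }
        )
    return CVResult(
        auc_per_repeat=aucs,
        tss_per_repeat=tsss,
        thresholds=thrs,
        splits=splits,
        n_resampled=n_resampled,
    )
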