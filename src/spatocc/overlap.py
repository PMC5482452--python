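"""Geographic niche-overlap statistics between two prediction surfaces.

Each surface is first normalized to a probability distribution over the
shared cells; overlap is then quantified by Schoener's D, the Hellinger
distance H, and Warren's I = 1 - H^2 / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from spatocc.mcmc import PredictionSurface

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


class OverlapError(ValueError):
    """Invalid overlap input."""


@dataclass
class OverlapResult:
    """Overlap statistics for a pair of normalized surfaces."""

    D: float
    H: float
    I: float
    n_cells_compared: int
    normalization_sums: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "schoeners_D": self.D,
            "hellinger_H": self.H,
            "warrens_I": self.I,
            "n_cells_compared": self.n_cells_compared,
            "normalization_sums": list(self.normalization_sums),
        }


def normalize_surface(surface: PredictionSurface | np.ndarray) -> np.ndarray:
    """Rescale a nonnegative surface so its cells sum to one."""
    values = (
        surface.prob_median if isinstance(surface, PredictionSurface) else np.asarray(surface, dtype=float)
    )
    if np.any(values < 0):
        raise OverlapError("surface has negative values")
    total = float(values.sum())
    if total <= 0:
        raise OverlapError("surface is all zero; cannot normalize")
    return values / total


def _check_normalized(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise OverlapError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise OverlapError(f"{name} is not normalized (sum={p.sum()!r})")
    return p


def schoeners_d(pX: np.ndarray, pY: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |pX_i - pY_i|; 1 identical, 0 disjoint."""
    pX = _check_normalized(pX, "pX")
    pY = _check_normalized(pY, "pY")
    if pX.shape != pY.shape:
        raise OverlapError("surfaces must share their cell set")
    return float(1.0 - 0.5 * np.abs(pX - pY).sum())


def hellinger_distance(pX: np.ndarray, pY: np.ndarray) -> float:
    """Hellinger distance H = sqrt(sum (sqrt(pX_i) - sqrt(pY_i))^2) in [0, sqrt(2)]."""
    pX = _check_normalized(pX, "pX")
    pY = _check_normalized(pY, "pY")
    if pX.shape != pY.shape:
        raise OverlapError("surfaces must share their cell set")
    return float(np.sqrt(np.sum((np.sqrt(pX) - np.sqrt(pY)) ** 2)))


def warrens_i(pX: np.ndarray, pY: np.ndarray) -> float:
    """Warren's I = 1 - H^2 / 2; 1 identical, 0 disjoint."""
    h = hellinger_distance(pX, pY)
    return float(1.0 - h * h / 2.0)


def compare_surfaces(
    surface_x: PredictionSurface | np.ndarray,
    surface_y: PredictionSurface | np.ndarray,
    mask: np.ndarray | None = None,
) -> OverlapResult:
    """Normalize two surfaces over their shared cells and compute D, H, I.

    ``mask`` restricts the comparison (e.g. cells valid in both surfaces);
    dropped cells are counted in the log, never imputed.
    """
    vx = (
        surface_x.prob_median
        if isinstance(surface_x, PredictionSurface)
        else np.asarray(surface_x, dtype=float)
    )
    vy = (
        surface_y.prob_median
        if isinstance(surface_y, PredictionSurface)
        else np.asarray(surface_y, dtype=float)
    )
    if vx.shape != vy.shape:
        raise OverlapError("surfaces must share their cell set")
    keep = np.isfinite(vx) & np.isfinite(vy)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d cells missing in at least one surface", dropped)
    sum_x = float(vx[keep].sum())
    sum_y = float(vy[keep].sum())
    px = normalize_surface(vx[keep])
    py = normalize_surface(vy[keep])
    h = hellinger_distance(px, py)
    return OverlapResult(
        D=schoeners_d(px, py),
        H=h,
        I=float(1.0 - h * h / 2.0),
        n_cells_compared=int(keep.sum()),
        normalization_sums=(sum_x, sum_y),
    )
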