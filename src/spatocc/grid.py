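"""Analysis lattice, adjacency and per-cell data preparation.

The lattice is a regular grid of square cells covering a bounding box in
projected coordinates (metres or abstract km).  Cell extents are half-open
``[x, x + cell_size) x [y, y + cell_size)`` with a lower-left origin, so a
point on an interior boundary belongs to the cell with the larger index.
Cell ids are row-major: ``cell_id = row * n_cols + col`` with row 0 at the
bottom (smallest y).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: sentinel returned for points outside the grid bounding box
OUT_OF_GRID = -1

#: absolute Pearson-correlation threshold above which a covariate pair is flagged
CORRELATION_FLAG_THRESHOLD = 0.6


class GridError(ValueError):
    """Invalid grid geometry or adjacency request."""


@dataclass(frozen=True)
class LatticeGrid:
    """Regular lattice of square cells plus symmetric neighbor structure.

    Parameters
    ----------
    origin
        ``(x0, y0)`` lower-left corner of the bounding box.
    cell_size
        Side length of the square cells (same units as the coordinates).
    n_rows, n_cols
        Lattice dimensions; partial edge cells are full members.
    adjacency
        ``(n_edges, 2)`` integer array of unique symmetric neighbor pairs
        ``(i, j)`` with ``i < j`` and no self-loops.
    """

    origin: tuple[float, float]
    cell_size: float
    n_rows: int
    n_cols: int
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "adjacency", adj)
        if adj.size:
            if adj.min() < 0 or adj.max() >= self.n_cells:
                raise GridError("adjacency references cell ids outside the grid")
            if np.any(adj[:, 0] == adj[:, 1]):
                raise GridError("adjacency contains self-loops")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def cell_centers(self) -> np.ndarray:
        """``(n_cells, 2)`` array of cell-center coordinates."""
        x0, y0 = self.origin
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        cx = x0 + (cols + 0.5) * self.cell_size
        cy = y0 + (rows + 0.5) * self.cell_size
        return np.column_stack([cx, cy])

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Symmetric 0/1 sparse adjacency matrix."""
        n = self.n_cells
        if not self.adjacency.size:
            return sparse.csr_matrix((n, n))
        i, j = self.adjacency.T
        data = np.ones(2 * len(i))
        return sparse.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )

    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_cells, dtype=np.int64)
        if self.adjacency.size:
            np.add.at(counts, self.adjacency.ravel(), 1)
        return counts

    def laplacian(self) -> sparse.csr_matrix:
        """Graph Laplacian ``D - A`` (the unscaled iCAR precision)."""
        a = self.adjacency_matrix()
        return sparse.diags(self.neighbor_counts().astype(float)) - a

    def components(self) -> tuple[int, np.ndarray]:
        """Connected components ``(n_components, labels)`` of the neighbor graph."""
        return connected_components(self.adjacency_matrix(), directed=False)


def build_grid(
    bbox: tuple[float, float, float, float],
    cell_size: float,
    scheme: str = "queen",
) -> LatticeGrid:
    """Tile a bounding box with square cells and attach adjacency.

    Cell counts per axis use ceiling arithmetic, so partial edge cells are
    included.  ``scheme`` selects the neighbor rule (``"queen"`` default,
    ``"rook"`` optional).
    """
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise GridError(f"degenerate bounding box {bbox!r}")
    if cell_size <= 0:
        raise GridError(f"cell_size must be positive, got {cell_size}")
    n_cols = math.ceil((xmax - xmin) / cell_size)
    n_rows = math.ceil((ymax - ymin) / cell_size)
    adjacency = _lattice_adjacency(n_rows, n_cols, scheme)
    return LatticeGrid(
        origin=(xmin, ymin),
        cell_size=float(cell_size),
        n_rows=n_rows,
        n_cols=n_cols,
        adjacency=adjacency,
    )


def _lattice_adjacency(n_rows: int, n_cols: int, scheme: str) -> np.ndarray:
    if scheme == "rook":
        offsets = [(0, 1), (1, 0)]
    elif scheme == "queen":
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    else:
        raise GridError(f"unknown adjacency scheme {scheme!r}; use 'rook' or 'queen'")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    pairs = []
    for dr, dc in offsets:
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < n_rows) & (c2 >= 0) & (c2 < n_cols)
        a = np.flatnonzero(ok)
        b = r2[ok] * n_cols + c2[ok]
        pairs.append(np.column_stack([np.minimum(a, b), np.maximum(a, b)]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.vstack(pairs)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def build_adjacency(grid: LatticeGrid, scheme: str = "queen") -> np.ndarray:
    """Recompute the symmetric neighbor-pair list of ``grid`` under ``scheme``."""
    return _lattice_adjacency(grid.n_rows, grid.n_cols, scheme)


def with_adjacency(grid: LatticeGrid, adjacency: np.ndarray) -> LatticeGrid:
    """Return a copy of ``grid`` carrying a different adjacency."""
    return replace(grid, adjacency=np.asarray(adjacency, dtype=np.int64).reshape(-1, 2))


def assign_points_to_cells(points: np.ndarray, grid: LatticeGrid) -> np.ndarray:
    """Map ``(x, y)`` points to cell ids under the half-open convention.

    Points outside the bounding box get the ``OUT_OF_GRID`` sentinel (-1)
    and a warning is logged; nothing is dropped silently.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    x0, y0 = grid.origin
    cols = np.floor((pts[:, 0] - x0) / grid.cell_size).astype(np.int64)
    rows = np.floor((pts[:, 1] - y0) / grid.cell_size).astype(np.int64)
    inside = (cols >= 0) & (cols < grid.n_cols) & (rows >= 0) & (rows < grid.n_rows)
    out = np.where(inside, rows * grid.n_cols + cols, OUT_OF_GRID)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d of %d points fall outside the grid bbox", n_out, len(pts))
    return out


def compute_effort(visit_cells: np.ndarray, grid: LatticeGrid) -> np.ndarray:
    """Per-cell visit counts: effort is the number of times a cell was visited."""
    cells = np.asarray(visit_cells, dtype=np.int64)
    if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
        bad = cells[(cells < 0) | (cells >= grid.n_cells)]
        raise GridError(f"unknown cell ids in visit records: {np.unique(bad)[:5]}")
    return np.bincount(cells, minlength=grid.n_cells).astype(np.int64)


def weighted_cell_average(
    values: np.ndarray,
    weights: np.ndarray,
    cell_ids: np.ndarray,
    grid: LatticeGrid,
) -> np.ndarray:
    """Per-cell weighted mean sum(w*v)/sum(w); cells without records are NaN."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    c = np.asarray(cell_ids, dtype=np.int64)
    if not (len(v) == len(w) == len(c)):
        raise GridError("values, weights and cell_ids must have equal length")
    if np.any(w <= 0):
        raise GridError("weights must be strictly positive")
    if c.size and (c.min() < 0 or c.max() >= grid.n_cells):
        raise GridError("cell ids out of range")
    wsum = np.bincount(c, weights=w, minlength=grid.n_cells)
    wvsum = np.bincount(c, weights=w * v, minlength=grid.n_cells)
    has_records = np.bincount(c, minlength=grid.n_cells) > 0
    if np.any(has_records & (wsum <= 0)):
        raise GridError("zero total weight in a cell with records")
    out = np.full(grid.n_cells, np.nan)
    out[has_records] = wvsum[has_records] / wsum[has_records]
    return out


@dataclass
class ScreeningReport:
    """Pairwise Pearson correlations between covariates, with flags at |r| >= 0.6.

    Flagged pairs are reported, never auto-dropped.
    """

    pairs: pd.DataFrame  # columns: var_a, var_b, r, flagged

    @property
    def flagged(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flagged"]]

    def to_dict(self) -> dict:
        return {"pairs": self.pairs.to_dict(orient="records")}


def prepare_covariates(
    raw: pd.DataFrame,
    flag_threshold: float = CORRELATION_FLAG_THRESHOLD,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Z-score standardize covariate columns and screen pairwise correlations.

    Rows with missing values are ignored for the statistics but retained
    (standardized with the complete-case mean/sd) in the output.

    Raises
    ------
    GridError
        If a covariate has zero variance (naming the column) or fewer than
        two complete rows are available.
    """
    if raw.shape[1] < 1:
        raise GridError("need at least one covariate column")
    if raw.shape[0] < 2:
        raise GridError("need at least two cells to standardize")
    std = raw.copy().astype(float)
    for col in std.columns:
        x = std[col].to_numpy()
        finite = np.isfinite(x)
        mu = x[finite].mean()
        sd = x[finite].std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise GridError(f"covariate {col!r} has zero variance")
        std[col] = (x - mu) / sd
    cols = list(std.columns)
    records = []
    for a_idx in range(len(cols)):
        for b_idx in range(a_idx + 1, len(cols)):
            a, b = cols[a_idx], cols[b_idx]
            xy = std[[a, b]].dropna().to_numpy()
            r = float(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]) if len(xy) > 1 else np.nan
            records.append(
                {"var_a": a, "var_b": b, "r": r, "flagged": bool(abs(r) >= flag_threshold)}
            )
    report = ScreeningReport(
        pairs=pd.DataFrame(records, columns=["var_a", "var_b", "r", "flagged"])
    )
    for rec in report.flagged.itertuples():
        logger.warning(
            "covariates %s and %s are highly correlated (r=%.3f >= %.2f)",
            rec.var_a, rec.var_b, rec.r, flag_threshold,
        )
    return std, report


@dataclass
class SiteDataset:
    """Per-cell ecological design and per-visit detection data.

    Attributes
    ----------
    grid
        The lattice the cells live on.
    X
        ``(n_cells, p)`` ecological design matrix (intercept column first,
        remaining columns standardized).
    x_names
        Column names of ``X`` (``x_names[0] == "intercept"``).
    W
        ``(n_visits, q)`` visit-level detection design matrix (intercept
        first; e.g. effort, sea state, wind).
    w_names
        Column names of ``W``.
    y
        ``(n_visits,)`` binary detections.
    visit_cell
        ``(n_visits,)`` cell id of each visit.
    visits
        ``(n_cells,)`` per-cell visit counts.
    screening_report
        Optional covariate-correlation screening report.
    """

    grid: LatticeGrid
    X: np.ndarray
    x_names: tuple[str, ...]
    W: np.ndarray
    w_names: tuple[str, ...]
    y: np.ndarray
    visit_cell: np.ndarray
    visits: np.ndarray
    screening_report: ScreeningReport | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        W = np.asarray(self.W, dtype=float)
        self.W = W if W.ndim == 2 else W.reshape(max(len(self.y), 1), -1)[: len(self.y)]
        self.y = np.asarray(self.y, dtype=np.int64)
        self.visit_cell = np.asarray(self.visit_cell, dtype=np.int64)
        self.visits = np.asarray(self.visits, dtype=np.int64)
        if self.X.shape[0] != self.grid.n_cells:
            raise GridError("X rows must align with grid cells")
        if len(self.x_names) != self.X.shape[1]:
            raise GridError("x_names length mismatch")
        if self.W.shape[0] != len(self.y) or len(self.y) != len(self.visit_cell):
            raise GridError("visit-level arrays must share their length")
        if len(self.w_names) != self.W.shape[1]:
            raise GridError("w_names length mismatch")
        if self.visit_cell.size and (
            self.visit_cell.min() < 0 or self.visit_cell.max() >= self.grid.n_cells
        ):
            raise GridError("visit references a cell outside the grid")
        if np.any((self.y != 0) & (self.y != 1)):
            raise GridError("detections must be binary")

    @property
    def n_cells(self) -> int:
        return self.grid.n_cells

    @property
    def n_visits(self) -> int:
        return len(self.y)

    def any_detection(self) -> np.ndarray:
        """Per-cell indicator: 1 if the cell has at least one detection."""
        out = np.zeros(self.n_cells, dtype=np.int64)
        np.maximum.at(out, self.visit_cell, self.y)
        return out

    def design_for(self, term_names: tuple[str, ...]) -> np.ndarray:
        """Columns of X for ``("intercept",) + term_names`` in that order."""
        idx = [self.x_names.index("intercept")]
        for name in term_names:
            if name == "intercept":
                continue
            if name not in self.x_names:
                raise GridError(f"unknown ecological term {name!r}")
            idx.append(self.x_names.index(name))
        return self.X[:, idx]

    def detection_design_for(self, term_names: tuple[str, ...]) -> np.ndarray:
        idx = [self.w_names.index("intercept")]
        for name in term_names:
            if name == "intercept":
                continue
            if name not in self.w_names:
                raise GridError(f"unknown detection term {name!r}")
            idx.append(self.w_names.index(name))
        return self.W[:, idx]

    def subset_cells(self, keep: np.ndarray) -> tuple["SiteDataset", np.ndarray]:
        """Restrict to a subset of cells (e.g. a CV training fold).

        Returns the reduced dataset (with the induced-subgraph adjacency and
        a degenerate 1 x n_keep grid relabeling) plus the original cell ids,
        so predictions can be mapped back.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep_ids = np.flatnonzero(keep)
        else:
            keep_ids = np.unique(keep)
        new_id = -np.ones(self.grid.n_cells, dtype=np.int64)
        new_id[keep_ids] = np.arange(len(keep_ids))
        adj = self.grid.adjacency
        if adj.size:
            mask = (new_id[adj[:, 0]] >= 0) & (new_id[adj[:, 1]] >= 0)
            sub_adj = new_id[adj[mask]]
        else:
            sub_adj = np.empty((0, 2), dtype=np.int64)
        sub_grid = LatticeGrid(
            origin=self.grid.origin,
            cell_size=self.grid.cell_size,
            n_rows=1,
            n_cols=len(keep_ids),
            adjacency=sub_adj,
        )
        vmask = new_id[self.visit_cell] >= 0
        sub = SiteDataset(
            grid=sub_grid,
            X=self.X[keep_ids],
            x_names=self.x_names,
            W=self.W[vmask],
            w_names=self.w_names,
            y=self.y[vmask],
            visit_cell=new_id[self.visit_cell[vmask]],
            visits=self.visits[keep_ids],
            screening_report=None,
        )
        return sub, keep_ids
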