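"""Grid aggregation of per-cell velocities and multi-view CTS orchestration.

Takes per-cell embedding coordinates (D = 2 or 3), velocity displacement
vectors in the same space, and cluster labels; lays a regular grid over each
2D perspective of the embedding; aggregates the cells in each grid rectangle
into a single velocity arrow whose starting cluster is decided by majority
vote; and runs the geometry pipeline per view, summing the per-view CTS
matrices into the final result.

For a 3D embedding the default perspectives are axes (0, 2) and (1, 2) —
i.e. dimension 1 vs 3 and dimension 2 vs 3 in 1-based axis naming.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    CentroidSet,
    CTSMatrix,
    SkipLog,
    VelocityArrow,
    compose_cts,
    distance_weights,
    score_arrows,
    sum_by_transition,
)

__all__ = [
    "GridConfig",
    "ViewSpec",
    "default_views",
    "project_view",
    "majority_vote",
    "build_grid_arrows",
    "compute_centroids",
    "multiview_cts",
]

ViewSpec = Tuple[int, int]


@dataclass(frozen=True)
class GridConfig:
    """Grid-overlay parameters.

    n_grid: grid rectangles per axis. min_cells: minimum cells a rectangle
    needs to emit an arrow. margin_frac: fractional expansion of the bounding
    box before gridding. arrow_scale: multiplier on the mean displacement.
    start_at: 'center' puts the arrow base at the rectangle center, 'mean' at
    the mean member position.
    """

    n_grid: int = 30
    min_cells: int = 2
    margin_frac: float = 0.02
    arrow_scale: float = 1.0
    start_at: str = "center"

    def __post_init__(self) -> None:
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.margin_frac < 0:
            raise ValueError("margin_frac must be >= 0")
        if self.arrow_scale <= 0:
            raise ValueError("arrow_scale must be > 0")
        if self.start_at not in ("center", "mean"):
            raise ValueError("start_at must be 'center' or 'mean'")


def _validate_view(view: ViewSpec, ndim: int) -> None:
    a, b = view
    if a == b:
        raise ValueError(f"view axes must be distinct, got {view}")
    if not (0 <= a < ndim and 0 <= b < ndim):
        raise ValueError(f"view {view} out of range for {ndim}-dimensional embedding")


def default_views(ndim: int) -> List[ViewSpec]:
    """Default perspectives: (0,2) and (1,2) for 3D, the single (0,1) for 2D."""
    if ndim == 3:
        return [(0, 2), (1, 2)]
    if ndim == 2:
        return [(0, 1)]
    raise ValueError(f"embedding must be 2- or 3-dimensional, got D={ndim}")


def view_id(view: ViewSpec) -> str:
    return f"view_{view[0]}x{view[1]}"


def project_view(
    embedding: pd.DataFrame, velocity: pd.DataFrame, view: ViewSpec
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Select the two view axes from embedding and velocity, preserving cell order."""
    ndim = embedding.shape[1]
    _validate_view(view, ndim)
    if velocity.shape[1] != ndim:
        raise ValueError("embedding and velocity dimensionality differ")
    pos = embedding.iloc[:, list(view)].copy()
    disp = velocity.iloc[:, list(view)].copy()
    return pos, disp


def majority_vote(labels) -> str:
    """Most frequent label; ties broken by the lexicographically smallest label."""
    counts = Counter(labels)
    if not counts:
        raise ValueError("majority vote over empty label set")
    best = max(counts.values())
    return min(label for label, n in counts.items() if n == best)


def build_grid_arrows(
    pos2d: pd.DataFrame,
    disp2d: pd.DataFrame,
    labels: pd.Series,
    cfg: GridConfig = GridConfig(),
    view: ViewSpec = (0, 1),
) -> List[VelocityArrow]:
    """Aggregate cells into one velocity arrow per occupied grid rectangle.

    The positional bounding box is expanded by ``margin_frac`` per side and
    partitioned into ``n_grid x n_grid`` equal rectangles. Every rectangle
    holding at least ``min_cells`` cells yields one arrow: base at the
    rectangle center (or mean member position), tip displaced by
    ``arrow_scale`` times the mean member displacement, starting cluster by
    majority vote over member labels.
    """
    pos = np.asarray(pos2d, dtype=float)
    disp = np.asarray(disp2d, dtype=float)
    lab = np.asarray(labels).astype(str)
    if len(pos) != len(disp) or len(pos) != len(lab):
        raise ValueError("positions, displacements and labels must align")
    if len(pos) == 0:
        return []

    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    span = hi - lo
    # zero-extent axes (all cells on a line/point) get unit span so the grid is well defined
    span = np.where(span > 0, span, 1.0)
    lo = lo - cfg.margin_frac * span
    hi = hi + cfg.margin_frac * span
    width = (hi - lo) / cfg.n_grid

    idx = np.floor((pos - lo) / width).astype(int)
    idx = np.clip(idx, 0, cfg.n_grid - 1)

    cells_by_rect: Dict[Tuple[int, int], List[int]] = {}
    for i, (gx, gy) in enumerate(idx):
        cells_by_rect.setdefault((int(gx), int(gy)), []).append(i)

    vid = view_id(view)
    arrows: List[VelocityArrow] = []
    for (gx, gy) in sorted(cells_by_rect):
        members = cells_by_rect[(gx, gy)]
        if len(members) < cfg.min_cells:
            continue
        if cfg.start_at == "center":
            start = lo + (np.array([gx, gy]) + 0.5) * width
        else:
            start = pos[members].mean(axis=0)
        end = start + cfg.arrow_scale * disp[members].mean(axis=0)
        arrows.append(
            VelocityArrow(
                view_id=vid,
                start=(float(start[0]), float(start[1])),
                end=(float(end[0]), float(end[1])),
                start_cluster=majority_vote(lab[members]),
                n_cells=len(members),
            )
        )
    return arrows


def compute_centroids(
    pos2d: pd.DataFrame, labels: pd.Series, view: ViewSpec = (0, 1)
) -> CentroidSet:
    """Per-cluster arithmetic mean of member coordinates in the view plane."""
    pos = np.asarray(pos2d, dtype=float)
    lab = np.asarray(labels).astype(str)
    if len(pos) != len(lab):
        raise ValueError("positions and labels must align")
    centroids: Dict[str, Tuple[float, float]] = {}
    for label in np.unique(lab):
        members = pos[lab == label]
        if len(members) == 0:
            raise ValueError(f"cluster {label!r} has no cells")
        mean = members.mean(axis=0)
        centroids[str(label)] = (float(mean[0]), float(mean[1]))
    return CentroidSet(view_id=view_id(view), centroids=centroids)


def multiview_cts(
    embedding: pd.DataFrame,
    velocity: pd.DataFrame,
    labels: pd.Series,
    views: Sequence[ViewSpec] | None = None,
    cfg: GridConfig = GridConfig(),
    convention: str = "endpoint",
    skip_log: SkipLog | None = None,
) -> CTSMatrix:
    """Run the full pipeline over one or more 2D perspectives.

    Per view: project, build grid arrows, compute centroids, score all
    (arrow, destination) pairs, sum by transition, weight by that view's
    centroid distances, and compose. The final CTS is the element-wise sum of
    the per-view CTS matrices; distance weights are only meaningful within a
    view's own 2D geometry, so weighting happens before cross-view pooling.
    """
    if views is None:
        views = default_views(embedding.shape[1])
    if len(views) == 0:
        raise ValueError("at least one view is required")
    cluster_order = sorted(set(np.asarray(labels).astype(str)))
    if len(cluster_order) < 2:
        raise ValueError("no transitions definable with fewer than 2 clusters")

    total: CTSMatrix | None = None
    for view in views:
        pos, disp = project_view(embedding, velocity, view)
        arrows = build_grid_arrows(pos, disp, labels, cfg, view)
        centroids = compute_centroids(pos, labels, view)
        scores = score_arrows(arrows, centroids, convention, skip_log)
        raw = sum_by_transition(scores, arrows, cluster_order)
        weights = distance_weights(centroids)
        view_cts = compose_cts(raw, weights, cluster_order)
        total = view_cts if total is None else total + view_cts
    assert total is not None
    return total
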