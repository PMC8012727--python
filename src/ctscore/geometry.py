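"""Composite transition scores from embedding-space velocity arrows.

Each grid-aggregated velocity arrow runs from a start point ``X`` to an end
point ``Y`` in a 2D view of the embedding. Its alignment with a candidate
destination cluster centroid ``Z`` is measured by the cosine of the triangle
angle (law of cosines), converted into a non-negative per-pair score

    S = (1 - cos theta) * |XY| / |XZ|        (endpoint convention)

so that longer arrows pointing at nearby centroids score highest. Scores are
summed by (starting cluster, destination cluster), weighted by a min-max
scaling of centroid distances per destination,

    w = 1 - (z - min(z)) / (max(z) - min(z)),

and composed into the K x K composite transition score (CTS) matrix

    CTS[j1, j2] = w[j1, j2] * sum_{arrows i starting in j1} S[i, j2].

Two angle conventions are offered because the score can be anchored either at
the arrow tip (``endpoint``, the default: angle at Y between Y->X and Y->Z,
scored with 1 - cos) or at the arrow origin (``origin``: angle at X between
X->Y and X->Z, scored with 1 + cos). Both are maximal when the arrow points
straight at the centroid and zero when it points straight away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Convention",
    "DegenerateGeometryError",
    "VelocityArrow",
    "CentroidSet",
    "PairScore",
    "DistanceWeightTable",
    "CTSMatrix",
    "SkipLog",
    "alignment_cosine",
    "arrow_destination_score",
    "score_arrows",
    "sum_by_transition",
    "distance_weights",
    "compose_cts",
    "log2_display",
]

CONVENTIONS = ("endpoint", "origin")
Convention = str
Point = Tuple[float, float]


class DegenerateGeometryError(ValueError):
    """A triangle side needed by the active convention has zero length."""


@dataclass(frozen=True)
class VelocityArrow:
    """One grid-aggregated velocity arrow in a 2D view.

    Attributes
    ----------
    view_id : str
        Identifier of the 2D perspective the arrow lives in.
    start, end : (float, float)
        Arrow base ``X`` and tip ``Y`` in embedding units.
    start_cluster : str
        Cluster assigned to the arrow by majority vote over the cells in its
        grid rectangle.
    n_cells : int
        Number of cells aggregated into the arrow (>= 1).
    """

    view_id: str
    start: Point
    end: Point
    start_cluster: str
    n_cells: int = 1

    def __post_init__(self) -> None:
        coords = (*self.start, *self.end)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError("arrow coordinates must be finite")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class CentroidSet:
    """Cluster label -> 2D centroid coordinates for one view."""

    view_id: str
    centroids: Mapping[str, Point]

    def __post_init__(self) -> None:
        for label, z in self.centroids.items():
            if not all(math.isfinite(c) for c in z):
                raise ValueError(f"non-finite centroid for cluster {label!r}")

    @property
    def labels(self) -> List[str]:
        return sorted(self.centroids)

    def __len__(self) -> int:
        return len(self.centroids)

    def __getitem__(self, label: str) -> Point:
        return self.centroids[label]


@dataclass(frozen=True)
class PairScore:
    """Score of one (arrow, destination cluster) pair."""

    arrow_index: int
    destination: str
    cos_theta: float
    score: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.cos_theta <= 1.0 + 1e-9):
            raise ValueError("cos_theta outside [-1, 1] tolerance")
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass
class DistanceWeightTable:
    """Centroid distance ``z`` and weight ``w`` per ordered (source, destination) pair.

    Self-pairs are excluded: including the zero self-distance would pin
    ``min(z)`` at 0 for every destination and no genuine source could reach
    weight 1.
    """

    pairs: Dict[Tuple[str, str], Tuple[float, float]]

    def weight(self, source: str, destination: str) -> float:
        return self.pairs[(source, destination)][1]

    def distance(self, source: str, destination: str) -> float:
        return self.pairs[(source, destination)][0]

    def weight_matrix(self, order: Sequence[str]) -> np.ndarray:
        k = len(order)
        out = np.zeros((k, k))
        for (j1, j2), (_, w) in self.pairs.items():
            out[order.index(j1), order.index(j2)] = w
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source": j1, "destination": j2, "distance": z, "weight": w}
            for (j1, j2), (z, w) in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["source", "destination", "distance", "weight"])


@dataclass
class CTSMatrix:
    """K x K composite transition scores with the unweighted raw totals."""

    labels: List[str]
    cts: np.ndarray
    raw: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        self.cts = np.asarray(self.cts, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.cts.shape != (k, k) or self.raw.shape != (k, k):
            raise ValueError("matrix shapes must be K x K for K labels")
        if (self.cts < 0).any() or (self.raw < 0).any():
            raise ValueError("CTS entries must be non-negative")
        if np.diag(self.cts).any() or np.diag(self.raw).any():
            raise ValueError("diagonal entries must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cts, index=self.labels, columns=self.labels)

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.labels, columns=self.labels)

    def __add__(self, other: "CTSMatrix") -> "CTSMatrix":
        if self.labels != other.labels:
            raise ValueError("cluster label orders differ")
        return CTSMatrix(list(self.labels), self.cts + other.cts, self.raw + other.raw)


@dataclass
class SkipLog:
    """Counts of arrows/pairs dropped for degenerate geometry.

    Silent data loss is a bug; callers surface these counts in run logs and
    manifests.
    """

    degenerate_arrows: int = 0
    degenerate_pairs: int = 0
    by_view: Dict[str, int] = field(default_factory=dict)

    def record(self, view_id: str, whole_arrow: bool) -> None:
        if whole_arrow:
            self.degenerate_arrows += 1
        self.degenerate_pairs += 1
        self.by_view[view_id] = self.by_view.get(view_id, 0) + 1

    def merge(self, other: "SkipLog") -> None:
        self.degenerate_arrows += other.degenerate_arrows
        self.degenerate_pairs += other.degenerate_pairs
        for view, n in other.by_view.items():
            self.by_view[view] = self.by_view.get(view, 0) + n


def _check_convention(convention: Convention) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


def _dist(a: Point, b: Point) -> float:
    return math.hypot(b[0] - a[0], b[1] - a[1])


def alignment_cosine(
    start: Point, end: Point, centroid: Point, convention: Convention = "endpoint"
) -> float:
    """Cosine of the arrow/centroid alignment angle, via the law of cosines.

    ``endpoint``: angle at the arrow tip Y between sides Y->X and Y->Z,
    cos = (|XY|^2 + |YZ|^2 - |XZ|^2) / (2 |XY| |YZ|). An arrow pointing
    straight at the centroid gives -1, straight away gives +1.

    ``origin``: angle at the arrow base X between X->Y and X->Z,
    cos = (|XY|^2 + |XZ|^2 - |YZ|^2) / (2 |XY| |XZ|). Straight at the
    centroid gives +1 (the perfectly-aligned limit), straight away -1.

    The result is clamped to [-1, 1]; near-collinear triangles can overshoot
    by ~1e-16 in floating point.

    Raises
    ------
    DegenerateGeometryError
        If a side used by the active convention has zero length.
    """
    _check_convention(convention)
    xy = _dist(start, end)
    xz = _dist(start, centroid)
    yz = _dist(end, centroid)
    if xy == 0.0:
        raise DegenerateGeometryError("zero-length arrow")
    if convention == "endpoint":
        if yz == 0.0:
            raise DegenerateGeometryError("arrow tip coincides with centroid")
        cos = (xy * xy + yz * yz - xz * xz) / (2.0 * xy * yz)
    else:
        if xz == 0.0:
            raise DegenerateGeometryError("arrow base coincides with centroid")
        cos = (xy * xy + xz * xz - yz * yz) / (2.0 * xy * xz)
    return min(1.0, max(-1.0, cos))


def arrow_destination_score(
    start: Point, end: Point, centroid: Point, convention: Convention = "endpoint"
) -> Tuple[float, float]:
    """Per-pair transition score S and its cosine.

    endpoint: S = (1 - cos) * |XY| / |XZ|;  origin: S = (1 + cos) * |XY| / |XZ|.
    Under either convention S >= 0, grows with arrow length, shrinks with
    distance to the centroid, peaks when the arrow points straight at the
    centroid and vanishes when it points straight away.

    Returns ``(cos_theta, score)``.
    """
    _check_convention(convention)
    xz = _dist(start, centroid)
    if xz == 0.0:
        raise DegenerateGeometryError("arrow base coincides with centroid")
    cos = alignment_cosine(start, end, centroid, convention)
    xy = _dist(start, end)
    if convention == "endpoint":
        s = (1.0 - cos) * xy / xz
    else:
        s = (1.0 + cos) * xy / xz
    return cos, max(0.0, s)


def score_arrows(
    arrows: Sequence[VelocityArrow],
    centroids: CentroidSet,
    convention: Convention = "endpoint",
    skip_log: SkipLog | None = None,
) -> List[PairScore]:
    """Score every (arrow, destination) pair, excluding self-transitions.

    Degenerate pairs (zero-length arrow, or the centroid coinciding with the
    side anchor) are omitted and counted in ``skip_log`` rather than failing
    the run.
    """
    _check_convention(convention)
    labels = set(centroids.centroids)
    scores: List[PairScore] = []
    for i, arrow in enumerate(arrows):
        if arrow.start_cluster not in labels:
            raise KeyError(
                f"arrow {i} has unknown start cluster {arrow.start_cluster!r}"
            )
        for dest in centroids.labels:
            if dest == arrow.start_cluster:
                continue
            try:
                cos, s = arrow_destination_score(
                    arrow.start, arrow.end, centroids[dest], convention
                )
            except DegenerateGeometryError:
                if skip_log is not None:
                    zero_arrow = _dist(arrow.start, arrow.end) == 0.0
                    skip_log.record(arrow.view_id, whole_arrow=zero_arrow)
                continue
            scores.append(PairScore(i, dest, cos, s))
    return scores


def sum_by_transition(
    pair_scores: Iterable[PairScore],
    arrows: Sequence[VelocityArrow],
    cluster_order: Sequence[str],
) -> np.ndarray:
    """Sum pair scores into a K x K raw-totals matrix.

    Entry (j1, j2) is the total score of arrows starting in cluster j1 toward
    destination j2; the diagonal stays zero by construction.
    """
    index = {label: i for i, label in enumerate(cluster_order)}
    totals = np.zeros((len(cluster_order), len(cluster_order)))
    for ps in pair_scores:
        arrow = arrows[ps.arrow_index]
        totals[index[arrow.start_cluster], index[ps.destination]] += ps.score
    return totals


def distance_weights(centroids: CentroidSet) -> DistanceWeightTable:
    """Min-max distance weights per destination cluster.

    For each destination j2 the Euclidean distances z from every *other*
    cluster centroid are rescaled to w = 1 - (z - min z)/(max z - min z):
    the nearest source cluster gets weight 1, the farthest weight 0. When all
    candidate distances coincide (notably K = 2) every weight is 1, since no
    relative penalty is definable from a single distance.
    """
    labels = centroids.labels
    if len(labels) < 2:
        raise ValueError("no transitions definable with fewer than 2 clusters")
    pairs: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for dest in labels:
        sources = [j for j in labels if j != dest]
        z = np.array([_dist(centroids[j], centroids[dest]) for j in sources])
        zmin, zmax = z.min(), z.max()
        if zmax == zmin:
            w = np.ones_like(z)
        else:
            w = 1.0 - (z - zmin) / (zmax - zmin)
        for j, zj, wj in zip(sources, z, w):
            pairs[(j, dest)] = (float(zj), float(wj))
    return DistanceWeightTable(pairs)


def compose_cts(
    raw_totals: np.ndarray,
    weights: DistanceWeightTable,
    cluster_order: Sequence[str],
) -> CTSMatrix:
    """CTS[j1, j2] = w[j1, j2] * raw[j1, j2], diagonal zero."""
    raw = np.asarray(raw_totals, dtype=float)
    k = len(cluster_order)
    if raw.shape != (k, k):
        raise ValueError(f"raw totals shape {raw.shape} != ({k}, {k})")
    for j1 in cluster_order:
        for j2 in cluster_order:
            if j1 != j2 and (j1, j2) not in weights.pairs:
                raise ValueError(f"missing weight for pair ({j1!r}, {j2!r})")
    wmat = weights.weight_matrix(list(cluster_order))
    return CTSMatrix(list(cluster_order), wmat * raw, raw.copy())


def log2_display(cts: CTSMatrix | np.ndarray) -> np.ndarray:
    """log2 of positive CTS entries; zeros become NaN (masked).

    Zero flow is qualitatively different from small flow, so zero entries are
    masked rather than pseudo-counted. The transform is monotone, preserving
    the ordering of positive entries.
    """
    mat = cts.cts if isinstance(cts, CTSMatrix) else np.asarray(cts, dtype=float)
    if (mat < 0).any():
        raise ValueError("CTS entries must be non-negative")
    out = np.full(mat.shape, np.nan)
    pos = mat > 0
    out[pos] = np.log2(mat[pos])
    return out
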