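"""Synthetic flow fields with known ground-truth cluster transitions.

Cells are drawn from isotropic Gaussian clusters in embedding space. Each
non-terminal cluster carries one or more directed transition edges; a cell in
such a cluster receives a displacement of fixed speed pointing from its own
position toward the destination cluster's *center parameter* (not the
empirical centroid, so the ground truth is independent of sampling noise),
plus isotropic Gaussian noise. Terminal clusters receive pure noise.

``evaluate_recovery`` then asks: over non-terminal source clusters, what
fraction have their true destination as the argmax of the corresponding CTS
row? This is the primary end-to-end statistic for the scoring pipeline.

A Poisson count-matrix generator with a controllable fraction of
marker-contaminated cells supports testing of the QC filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import CTSMatrix
from .preprocess import (
    CountMatrix,
    DEFAULT_FORBIDDEN,
)
import scipy.sparse as sp

__all__ = [
    "FlowScenario",
    "SyntheticDataset",
    "chain_scenario",
    "simulate_embedding",
    "simulate_velocity",
    "simulate_dataset",
    "simulate_counts",
    "evaluate_recovery",
]


@dataclass
class FlowScenario:
    """Ground-truth generative description of a synthetic velocity landscape.

    centers: cluster label -> D-dimensional center (embedding units).
    n_cells: cells per cluster. spread: isotropic Gaussian s.d. around each
    center. edges: source -> list of (destination, speed); clusters with no
    entry are terminal. noise_sd: s.d. of isotropic displacement noise.
    """

    centers: Dict[str, np.ndarray]
    n_cells: Dict[str, int]
    spread: float
    edges: Dict[str, List[Tuple[str, float]]]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.centers = {k: np.asarray(v, dtype=float) for k, v in self.centers.items()}
        dims = {v.shape for v in self.centers.values()}
        if len(dims) != 1:
            raise ValueError("all cluster centers must share one dimensionality")
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for label, n in self.n_cells.items():
            if n < 1:
                raise ValueError(f"cluster {label!r} must have >= 1 cells")
            if label not in self.centers:
                raise ValueError(f"n_cells given for unknown cluster {label!r}")
        for src, targets in self.edges.items():
            if src not in self.centers:
                raise ValueError(f"edge from unknown cluster {src!r}")
            for dest, speed in targets:
                if dest not in self.centers:
                    raise ValueError(f"edge toward unknown cluster {dest!r}")
                if speed <= 0:
                    raise ValueError("edge speed must be > 0")

    @property
    def ndim(self) -> int:
        return next(iter(self.centers.values())).shape[0]

    @property
    def labels(self) -> List[str]:
        return sorted(self.centers)

    def to_dict(self) -> dict:
        return {
            "centers": {k: [float(x) for x in v] for k, v in self.centers.items()},
            "n_cells": dict(self.n_cells),
            "spread": self.spread,
            "edges": {
                s: [[d, float(v)] for d, v in targets]
                for s, targets in self.edges.items()
            },
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FlowScenario":
        return cls(
            centers={k: np.asarray(v, dtype=float) for k, v in data["centers"].items()},
            n_cells={k: int(v) for k, v in data["n_cells"].items()},
            spread=float(data["spread"]),
            edges={
                s: [(str(d), float(v)) for d, v in targets]
                for s, targets in data.get("edges", {}).items()
            },
            noise_sd=float(data.get("noise_sd", 0.0)),
            seed=int(data.get("seed", 0)),
        )


@dataclass
class SyntheticDataset:
    """Aligned embedding/velocity/label tables plus the generating scenario."""

    embedding: pd.DataFrame
    velocity: pd.DataFrame
    labels: pd.Series
    scenario: FlowScenario


# Chain-scenario geometry: four well-separated Gaussian clusters on a directed
# chain A -> B -> C -> D. In 3D the centers are placed so that both default
# perspectives (axes 0x2 and 1x2) keep the clusters apart.
_CHAIN_CENTERS = {
    2: {
        "A": (0.0, 0.0),
        "B": (5.0, 0.0),
        "C": (10.0, 5.0),
        "D": (5.0, 10.0),
    },
    3: {
        "A": (0.0, 0.0, 0.0),
        "B": (8.0, 6.0, 0.0),
        "C": (8.0, 12.0, 8.0),
        "D": (0.0, 18.0, 8.0),
    },
}


def chain_scenario(
    ndim: int = 3,
    n_cells: int = 200,
    spread: float = 1.0,
    speed: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> FlowScenario:
    """Default 4-cluster chain A -> B -> C -> D (D terminal).

    The defaults put the cluster spread at 0.2x the minimum center distance
    and the displacement noise at 0.1x the edge speed, with 200 cells per
    cluster — a clearly structured but non-trivial flow field.
    """
    if ndim not in _CHAIN_CENTERS:
        raise ValueError("chain scenario is defined for 2 or 3 dimensions")
    centers = {k: np.asarray(v) for k, v in _CHAIN_CENTERS[ndim].items()}
    return FlowScenario(
        centers=centers,
        n_cells={k: n_cells for k in centers},
        spread=spread,
        edges={"A": [("B", speed)], "B": [("C", speed)], "C": [("D", speed)]},
        noise_sd=noise_sd,
        seed=seed,
    )


def _rng(scenario: FlowScenario, stream: int) -> np.random.Generator:
    # independent streams for positions vs displacements, both tied to the seed
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, stream]))


def simulate_embedding(scenario: FlowScenario) -> Tuple[pd.DataFrame, pd.Series]:
    """Draw cell positions from per-cluster isotropic Gaussians."""
    rng = _rng(scenario, 0)
    coords: List[np.ndarray] = []
    labels: List[str] = []
    for label in scenario.labels:
        n = scenario.n_cells[label]
        coords.append(
            scenario.centers[label] + scenario.spread * rng.standard_normal((n, scenario.ndim))
        )
        labels.extend([label] * n)
    pos = np.vstack(coords)
    cells = [f"cell{i:05d}" for i in range(len(pos))]
    emb = pd.DataFrame(pos, index=cells, columns=[f"dim{d}" for d in range(scenario.ndim)])
    return emb, pd.Series(labels, index=cells, name="cluster")


def simulate_velocity(
    embedding: pd.DataFrame, labels: pd.Series, scenario: FlowScenario
) -> pd.DataFrame:
    """Displacements of fixed speed toward each cell's destination center, plus noise.

    Cells in clusters with multiple outgoing edges are split between
    destinations round-robin in cell order; terminal-cluster cells get pure
    noise (zero displacement when noise_sd = 0).
    """
    rng = _rng(scenario, 1)
    pos = embedding.to_numpy()
    lab = labels.to_numpy().astype(str)
    disp = np.zeros_like(pos)
    for src in scenario.labels:
        members = np.where(lab == src)[0]
        targets = scenario.edges.get(src, [])
        if not targets:
            continue
        for k, i in enumerate(members):
            dest, speed = targets[k % len(targets)]
            direction = scenario.centers[dest] - pos[i]
            norm = np.linalg.norm(direction)
            if norm > 0:
                disp[i] = speed * direction / norm
    if scenario.noise_sd > 0:
        disp = disp + scenario.noise_sd * rng.standard_normal(disp.shape)
    return pd.DataFrame(disp, index=embedding.index, columns=embedding.columns)


def simulate_dataset(scenario: FlowScenario) -> SyntheticDataset:
    """Embedding, velocity and labels for one scenario; bit-reproducible."""
    emb, labels = simulate_embedding(scenario)
    vel = simulate_velocity(emb, labels, scenario)
    return SyntheticDataset(emb, vel, labels, scenario)


DEFAULT_GENE_PANEL = (
    DEFAULT_FORBIDDEN
    + ("IGHV1-69", "IGKC", "IGLL5", "TRBV7-2", "IGHM")
    + ("CD19", "MS4A1", "TCL1A", "CD27", "CD38")
    + tuple(f"GENE{i}" for i in range(40))
)


def simulate_counts(
    n_cells: int,
    gene_panel: Sequence[str] = DEFAULT_GENE_PANEL,
    seed: int = 0,
    forbidden_fraction: float = 0.0,
    forbidden_genes: Sequence[str] = DEFAULT_FORBIDDEN,
    base_rate: float = 2.0,
) -> CountMatrix:
    """Poisson toy count matrix for exercising the QC filter.

    Ordinary genes get independent Poisson(base_rate) counts in every cell.
    Forbidden-marker genes are zero except in a ``forbidden_fraction`` of
    cells, which receive Poisson(base_rate) + 1 counts there (guaranteeing a
    nonzero marker transcript, so those cells must fail QC criterion (i)).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= forbidden_fraction <= 1.0):
        raise ValueError("forbidden_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    genes = list(dict.fromkeys(gene_panel))
    forbidden = set(forbidden_genes)
    mat = np.zeros((len(genes), n_cells), dtype=np.int64)
    n_contam = int(round(forbidden_fraction * n_cells))
    contaminated = rng.choice(n_cells, size=n_contam, replace=False) if n_contam else []
    for gi, gene in enumerate(genes):
        if gene in forbidden:
            if len(contaminated):
                mat[gi, contaminated] = rng.poisson(base_rate, size=len(contaminated)) + 1
        else:
            mat[gi, :] = rng.poisson(base_rate, size=n_cells)
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]
    return CountMatrix(genes, barcodes, sp.csr_matrix(mat))


def evaluate_recovery(cts: CTSMatrix, scenario: FlowScenario) -> float:
    """Fraction of non-terminal sources whose argmax-CTS destination is true.

    A tied argmax counts as failure. With multi-destination sources, success
    means the top-1 destination is any of the true destinations.
    """
    sources = [s for s, targets in scenario.edges.items() if targets]
    if not sources:
        return 1.0
    missing = set(scenario.labels) - set(cts.labels)
    if missing:
        raise ValueError(f"CTS matrix lacks scenario clusters {sorted(missing)}")
    hits = 0
    for src in sources:
        row = cts.cts[cts.labels.index(src)].copy()
        row[cts.labels.index(src)] = -np.inf
        best = row.max()
        if best <= 0 or (row == best).sum() > 1:
            continue  # no flow or ambiguous argmax: failure
        top = cts.labels[int(row.argmax())]
        truth = {dest for dest, _ in scenario.edges[src]}
        if top in truth:
            hits += 1
    return hits / len(sources)
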