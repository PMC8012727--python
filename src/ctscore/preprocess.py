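"""B-cell single-cell QC filtering and immunoglobulin/TCR gene pruning.

Cell selection on a raw transcript count matrix proceeds in three fixed
stages: (i) drop cells expressing any transcript of a forbidden non-B-cell
marker panel (CD3E, GNLY, CD14, FCER1A, FCGR3A, LYZ, PPBP, CD8A); (ii) drop
cells detecting fewer than 200 distinct genes; then drop cells whose total
transcript count exceeds the top-1% nearest-rank quantile of the stage-(i)/(ii)
survivors — such cells tend to carry multiple immunoglobulin V-gene families
per barcode, indicating cell clumps.

Variable-gene pruning removes clonotype-specific immunoglobulin and T-cell
receptor genes from an ordered variable-gene list so that dimensionality
reduction does not cluster cells by antibody class or V-gene usage: all Ig
V/D/J genes (prefix regex ``IG[HKL][VDJ]``), TCR constant/variable genes
(``TR[ABGD][CV]``), the IGLL surrogate-light-chain genes, and an explicit
constant-region list (IGHM, IGHD, IGHE, IGHA1-2, IGHG1-4, IGKC, IGLC1-7, and
AC233755.1 which encodes IGHV4-38-2).

Note on the forbidden panel: the NK marker is FCGR3A (CD16); a strict mode is
available that uses the symbol GCGR3A instead, which matches no standard
human gene and therefore removes no cells on standard annotations.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

import re

__all__ = [
    "CountMatrix",
    "QCConfig",
    "PruningRules",
    "FilterReport",
    "FormatError",
    "read_counts",
    "write_counts",
    "filter_cells",
    "prune_variable_genes",
]

DEFAULT_FORBIDDEN = ("CD3E", "GNLY", "CD14", "FCER1A", "FCGR3A", "LYZ", "PPBP", "CD8A")
STRICT_FORBIDDEN = ("CD3E", "GNLY", "CD14", "FCER1A", "GCGR3A", "LYZ", "PPBP", "CD8A")

DEFAULT_PATTERNS = ("IG[HKL][VDJ]", "TR[ABGD][CV]", "IGLL")
DEFAULT_EXPLICIT = (
    "IGHM", "IGHD", "IGHE", "IGHA1", "IGHA2",
    "IGHG1", "IGHG2", "IGHG3", "IGHG4",
    "IGKC", "IGLC1", "IGLC2", "IGLC3", "IGLC4", "IGLC5", "IGLC6", "IGLC7",
    "AC233755.1",
)


class FormatError(ValueError):
    """A counts file could not be parsed as its declared format."""


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer transcript counts (sparse CSR)."""

    genes: List[str]
    barcodes: List[str]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("cell barcodes must be unique")
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape inconsistent with gene/barcode lists")
        if self.matrix.nnz and (self.matrix.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


@dataclass(frozen=True)
class QCConfig:
    """Cell-selection thresholds.

    strict_symbols reproduces the printed forbidden panel verbatim (GCGR3A)
    instead of the intended NK marker FCGR3A.
    """

    forbidden_genes: Tuple[str, ...] = DEFAULT_FORBIDDEN
    min_genes: int = 200
    top_count_percentile: float = 0.01
    strict_symbols: bool = False

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if not (0.0 <= self.top_count_percentile < 1.0):
            raise ValueError("top_count_percentile must be in [0, 1)")
        if self.strict_symbols and self.forbidden_genes == DEFAULT_FORBIDDEN:
            object.__setattr__(self, "forbidden_genes", STRICT_FORBIDDEN)


@dataclass(frozen=True)
class PruningRules:
    """Regex prefixes and explicit symbols to drop from a variable-gene list.

    Patterns are anchored at the symbol start: ``IG[HKL][VDJ]`` must catch
    IGHV1-69 and friends, while unanchored matching would also hit unrelated
    symbols containing the substring.
    """

    patterns: Tuple[str, ...] = DEFAULT_PATTERNS
    explicit: Tuple[str, ...] = DEFAULT_EXPLICIT

    def matches(self, symbol: str) -> bool:
        if symbol in self.explicit:
            return True
        return any(re.match(p, symbol) for p in self.patterns)


@dataclass
class FilterReport:
    """Outcome of the three-stage cell filter."""

    n_input: int
    removed_forbidden: int
    removed_min_genes: int
    removed_top_counts: int
    retained: List[str]
    missing_forbidden_genes: List[str] = field(default_factory=list)
    total_count_threshold: float | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("forbidden_gene_expression", self.removed_forbidden),
            ("min_distinct_genes", self.removed_min_genes),
            ("top_total_count", self.removed_top_counts),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_cells"])


def _open_maybe_gzip(path: str | Path) -> IO[bytes]:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rb")
    return open(p, "rb")


def _read_sidecar(path: str | Path, what: str) -> List[str]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: cannot parse {what} file ({exc})") from exc
    # 10x features files carry (id, symbol, type); use the symbol column when present
    col = 1 if (what == "features" and df.shape[1] >= 2) else 0
    return df.iloc[:, col].astype(str).tolist()


def read_counts(
    mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Load a 10x-style MatrixMarket triplet (plain or gzip) into a CountMatrix.

    Raises FormatError naming the offending file on malformed headers,
    non-integer entries, or dimension mismatches against the sidecars.
    """
    try:
        with _open_maybe_gzip(mtx_path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{mtx_path}: malformed MatrixMarket file ({exc})") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and not np.all(np.mod(mat.data, 1) == 0):
        raise FormatError(f"{mtx_path}: non-integer count entries")
    mat = mat.astype(np.int64)

    genes = _read_sidecar(features_path, "features")
    barcodes = _read_sidecar(barcodes_path, "barcodes")
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix declares {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix declares {mat.shape[1]} columns"
        )
    return CountMatrix(genes, barcodes, mat)


def write_counts(counts: CountMatrix, out_dir: str | Path, gzipped: bool = False) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv triplet into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    mtx_path = out / f"matrix.mtx{suffix}"
    if gzipped:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, sp.coo_matrix(counts.matrix), field="integer")
    else:
        scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(counts.matrix), field="integer")

    def _write_lines(lines: Sequence[str], path: Path) -> None:
        text = "".join(line + "\n" for line in lines).encode()
        if gzipped:
            with gzip.open(path, "wb") as fh:
                fh.write(text)
        else:
            path.write_bytes(text)

    _write_lines(counts.genes, out / f"features.tsv{suffix}")
    _write_lines(counts.barcodes, out / f"barcodes.tsv{suffix}")


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """ceil(q * n)-th order statistic (1-based), the nearest-rank quantile."""
    n = len(values)
    k = max(1, math.ceil(q * n))
    return float(np.sort(values)[k - 1])


def filter_cells(counts: CountMatrix, cfg: QCConfig = QCConfig()) -> FilterReport:
    """Apply the three-stage cell selection; order is fixed and matters.

    Forbidden genes absent from the matrix are treated as all-zero and
    reported in the returned FilterReport. The top-count quantile is computed
    over the survivors of stages (i)+(ii) only, and removal uses strict
    inequality, so re-running the filter on its own survivors removes nobody.
    """
    n = counts.n_cells
    if n == 0:
        return FilterReport(0, 0, 0, 0, [], list(cfg.forbidden_genes))

    gene_index = {g: i for i, g in enumerate(counts.genes)}
    present = [g for g in cfg.forbidden_genes if g in gene_index]
    missing = [g for g in cfg.forbidden_genes if g not in gene_index]

    keep = np.ones(n, dtype=bool)
    # stage 1: any forbidden-marker transcript disqualifies the cell
    if present:
        rows = counts.matrix[[gene_index[g] for g in present], :]
        contaminated = np.asarray((rows > 0).sum(axis=0)).ravel() > 0
    else:
        contaminated = np.zeros(n, dtype=bool)
    removed_forbidden = int(contaminated.sum())
    keep &= ~contaminated

    # stage 2: minimum number of distinct detected genes
    genes_per_cell = np.asarray((counts.matrix > 0).sum(axis=0)).ravel()
    too_few = keep & (genes_per_cell < cfg.min_genes)
    removed_min_genes = int(too_few.sum())
    keep &= ~too_few

    # stage 3: top-percentile total-count removal among survivors
    removed_top = 0
    threshold: float | None = None
    if cfg.top_count_percentile > 0 and keep.any():
        totals = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
        threshold = _nearest_rank_quantile(
            totals[keep], 1.0 - cfg.top_count_percentile
        )
        clumps = keep & (totals > threshold)
        removed_top = int(clumps.sum())
        keep &= ~clumps

    retained = [bc for bc, k in zip(counts.barcodes, keep) if k]
    return FilterReport(
        n_input=n,
        removed_forbidden=removed_forbidden,
        removed_min_genes=removed_min_genes,
        removed_top_counts=removed_top,
        retained=retained,
        missing_forbidden_genes=missing,
        total_count_threshold=threshold,
    )


def prune_variable_genes(
    gene_list: Sequence[str], rules: PruningRules = PruningRules()
) -> List[str]:
    """Drop Ig/TCR symbols from an ordered variable-gene list, preserving order.

    Idempotent: pruning an already-pruned list is the identity.
    """
    return [g for g in gene_list if not rules.matches(g)]
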