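"""Readers and writers for the tabular interchange formats.

Embedding, velocity and label tables are headered TSV/CSV with the cell
identifier in the first column. The separator is inferred from the file
extension (.csv -> comma, anything else -> tab).
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "read_embedding",
    "read_velocity",
    "read_labels",
    "validate_alignment",
    "write_matrix_tsv",
]


class ValidationError(ValueError):
    """Inputs are structurally readable but mutually inconsistent."""


class FormatError(ValueError):
    """A file could not be parsed as its declared format."""


def _sep(path: str | Path) -> str:
    name = str(path)
    return "," if name.endswith(".csv") or name.endswith(".csv.gz") else "\t"


def _read_indexed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_sep(path), index_col=0)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"{path}: duplicate cell identifiers, e.g. {dups}")
    df.index = df.index.astype(str)
    return df


def _read_numeric(path: str | Path) -> pd.DataFrame:
    df = _read_indexed(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value ({exc})") from exc
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError(f"{path}: non-finite coordinates")
    if df.shape[1] not in (2, 3):
        raise ValidationError(
            f"{path}: expected 2 or 3 coordinate columns, found {df.shape[1]}"
        )
    return df


def read_embedding(path: str | Path) -> pd.DataFrame:
    """Cells x D embedding coordinates, indexed by cell identifier."""
    return _read_numeric(path)


def read_velocity(path: str | Path) -> pd.DataFrame:
    """Cells x D velocity displacement vectors, indexed by cell identifier."""
    return _read_numeric(path)


def read_labels(path: str | Path) -> pd.Series:
    """Cell -> cluster label assignment (first data column of the table)."""
    df = _read_indexed(path)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no label column")
    return df.iloc[:, 0].astype(str)


def validate_alignment(
    embedding: pd.DataFrame, velocity: pd.DataFrame, labels: pd.Series
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Check the three tables cover the same cells; reorder to the embedding.

    Raises ValidationError naming example missing/extra cells on mismatch.
    """
    cells = embedding.index
    for name, idx in (("velocity", velocity.index), ("labels", labels.index)):
        missing = cells.difference(idx)
        extra = idx.difference(cells)
        if len(missing) or len(extra):
            parts = []
            if len(missing):
                parts.append(f"missing from {name}: {missing.tolist()[:5]}")
            if len(extra):
                parts.append(f"extra in {name}: {extra.tolist()[:5]}")
            raise ValidationError(f"cell sets differ ({'; '.join(parts)})")
    if embedding.shape[1] != velocity.shape[1]:
        raise ValidationError(
            f"embedding is {embedding.shape[1]}-D but velocity is {velocity.shape[1]}-D"
        )
    return embedding, velocity.loc[cells], labels.loc[cells]


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Labelled matrix as TSV: header row of destination labels, first column sources."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="source")
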