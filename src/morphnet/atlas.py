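"""Region tables and dense matrix I/O.

A cortical parcellation is represented as a *region table*: one row per
region with an integer id, a name, a hemisphere (L/R), and a class label
``gyral``, ``sulcal``, or ``ambiguous``.  Ambiguous regions (those spanning
both a gyral crown and a sulcal bank) are carried through I/O but excluded
from network construction, which operates on the retained gyral + sulcal
regions only.

The canonical node ordering used by every downstream module is: gyral
regions first (ascending ``region_id``), then sulcal regions (ascending
``region_id``).  This fixes the block layout of the gyri-gyri (G-G),
sulci-sulci (S-S), and gyri-sulci (G-S) subnetworks deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REGION_CLASSES",
    "REQUIRED_COLUMNS",
    "RegionTableError",
    "MatrixParseError",
    "Matrix",
    "load_region_table",
    "validate_region_table",
    "write_region_table",
    "retained_indices",
    "read_matrix",
    "write_matrix",
]

REGION_CLASSES = frozenset({"gyral", "sulcal", "ambiguous"})
REQUIRED_COLUMNS = ("region_id", "name", "hemisphere", "region_class")
HEMISPHERES = frozenset({"L", "R"})


class RegionTableError(ValueError):
    """A region table violates the format contract."""


class MatrixParseError(ValueError):
    """A delimited matrix file could not be parsed."""


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a region table.

    Class labels are lowercased but deliberately *not* stripped of
    whitespace: a label like ``"gyral "`` is rejected rather than silently
    repaired, so mislabeled atlases fail loudly.

    Returns a copy with ``region_id`` as int and ``region_class``
    lowercased.  Raises :class:`RegionTableError` naming the offending row
    on any violation; emits a warning when fewer than 2 gyral or 2 sulcal
    regions are present (downstream subnetwork analyses need both).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise RegionTableError(f"region table missing column(s): {missing}")

    out = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    out = out.reset_index(drop=True)

    ids = []
    for row, raw in enumerate(out["region_id"]):
        try:
            val = int(raw)
        except (TypeError, ValueError):
            raise RegionTableError(
                f"row {row}: region_id {raw!r} is not an integer"
            ) from None
        if val < 0:
            raise RegionTableError(f"row {row}: region_id {val} is negative")
        ids.append(val)
    out["region_id"] = ids

    dup = out["region_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise RegionTableError(
            f"row {row}: duplicate region_id {out['region_id'].iloc[row]}"
        )

    hemi = out["hemisphere"].astype(str)
    bad = ~hemi.isin(HEMISPHERES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RegionTableError(
            f"row {row}: hemisphere {hemi.iloc[row]!r} not in {sorted(HEMISPHERES)}"
        )
    out["hemisphere"] = hemi

    cls = out["region_class"].astype(str).str.lower()
    bad = ~cls.isin(REGION_CLASSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RegionTableError(
            f"row {row}: region_class {out['region_class'].iloc[row]!r} "
            f"not in {sorted(REGION_CLASSES)}"
        )
    out["region_class"] = cls

    n_gyral = int((cls == "gyral").sum())
    n_sulcal = int((cls == "sulcal").sum())
    if n_gyral < 2 or n_sulcal < 2:
        warnings.warn(
            f"region table has {n_gyral} gyral and {n_sulcal} sulcal regions; "
            "subnetwork analyses need at least 2 of each",
            UserWarning,
            stacklevel=2,
        )
    return out


def load_region_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated region table with a mandatory header row."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_region_table(table)


def write_region_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a region table as TSV (inverse of :func:`load_region_table`)."""
    validate_region_table(table).to_csv(path, sep="\t", index=False)


def retained_indices(table: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Region ids retained for analysis, split by class.

    Ambiguous regions are dropped.  Returns ``(gyral_ids, sulcal_ids)``,
    each sorted ascending by region id; together they partition the
    non-ambiguous regions.  Warns when both lists are empty.
    """
    table = validate_region_table(table)
    gyral = sorted(table.loc[table["region_class"] == "gyral", "region_id"])
    sulcal = sorted(table.loc[table["region_class"] == "sulcal", "region_id"])
    if not gyral and not sulcal:
        warnings.warn(
            "no gyral or sulcal regions retained (all ambiguous)",
            UserWarning,
            stacklevel=2,
        )
    return [int(i) for i in gyral], [int(i) for i in sulcal]


@dataclass
class Matrix:
    """Dense numeric matrix with optional row/column labels."""

    values: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> None:
    """Write a dense matrix as TSV with 12 significant digits.

    Labels are either both present or both absent.  When present, the
    first line holds an empty corner cell followed by column labels, and
    each data line starts with its row label.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix entries must be finite")
    if (row_labels is None) != (col_labels is None):
        raise ValueError("row and column labels must be given together")
    if row_labels is not None:
        if len(row_labels) != values.shape[0] or len(col_labels) != values.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
    lines = []
    if col_labels is not None:
        lines.append("\t".join([""] + [str(c) for c in col_labels]))
    for i in range(values.shape[0]):
        cells = [format(v, ".12g") for v in values[i]]
        if row_labels is not None:
            cells = [str(row_labels[i])] + cells
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_matrix(path: str | Path) -> Matrix:
    """Read a TSV matrix written by :func:`write_matrix`.

    Labels are auto-detected: if the first cell of the first line is empty
    or non-numeric, the first line is taken as column labels and the first
    column as row labels.  Ragged rows, non-numeric cells, and non-finite
    entries raise :class:`MatrixParseError` with the row/column position.
    """
    text = Path(path).read_text()
    rows = [line.split("\t") for line in text.splitlines() if line != ""]
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix file")

    labeled = not _is_number(rows[0][0])
    col_labels = row_labels = None
    if labeled:
        col_labels = [c for c in rows[0][1:]]
        rows = rows[1:]
        row_labels = []

    data = []
    width = None
    for i, cells in enumerate(rows):
        if labeled:
            row_labels.append(cells[0])
            cells = cells[1:]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise MatrixParseError(
                f"{path}: row {i} has {len(cells)} cells, expected {width}"
            )
        parsed = []
        for j, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: row {i}, column {j}: non-numeric cell {cell!r}"
                ) from None
            if not np.isfinite(v):
                raise MatrixParseError(
                    f"{path}: row {i}, column {j}: non-finite entry {cell!r}"
                )
            parsed.append(v)
        data.append(parsed)
    values = np.asarray(data, dtype=float)
    if labeled and len(col_labels) != values.shape[1]:
        raise MatrixParseError(
            f"{path}: {len(col_labels)} column labels for {values.shape[1]} columns"
        )
    return Matrix(values=values, row_labels=row_labels, col_labels=col_labels)
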