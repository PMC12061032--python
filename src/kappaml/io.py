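"""Reading and writing rating tables.

Two layouts are supported:

* two-column — one row per case, first column rater A's label, second
  rater B's (header optional);
* contingency — a square table of non-negative integer counts with
  matching row and column labels; rows are rater A, columns rater B.
  The table is expanded to case-level pairs in row-major label order,
  which is immaterial to every statistic computed here.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyRatingsError, ParseError
from .ratings import MISSING_SENTINELS, PairedRatings

logger = logging.getLogger(__name__)

__all__ = ["read_ratings", "write_ratings", "ratings_from_contingency"]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _looks_like_header(rows: list[list[str]]) -> bool:
    # Treat the first row as a header when neither of its cells reappears
    # as a label in the remaining rows (and there are remaining rows).
    if len(rows) < 2:
        return False
    head = set(rows[0])
    body = {cell for row in rows[1:] for cell in row}
    return head.isdisjoint(body)


def read_ratings(
    path: str | Path,
    *,
    contingency: bool = False,
    categories: tuple | None = None,
    delimiter: str | None = None,
    header: bool | None = None,
) -> PairedRatings:
    """Read paired ratings from a delimited text file.

    ``header=None`` auto-detects a header row in two-column files; pass
    True/False to force.  Cells that are empty or one of the usual NA
    spellings are treated as missing and dropped pairwise (logged).
    Contingency tables must be square with matching row/column labels and
    integer counts; ``header`` is ignored for them (always labelled).
    """
    path = Path(path)
    if contingency:
        return _read_contingency(path, _delimiter_for(path, delimiter))

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_delimiter_for(path, delimiter))
        rows = []
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue  # skip blank lines
            if len(row) != 2:
                raise ParseError(
                    f"expected 2 columns, found {len(row)}", line=lineno
                )
            rows.append([cell.strip() for cell in row])
    if not rows:
        raise EmptyRatingsError(f"{path} contains no rating rows")
    if header is None:
        header = _looks_like_header(rows)
    if header:
        rows = rows[1:]
    if not rows:
        raise EmptyRatingsError(f"{path} contains a header but no rating rows")
    a = [row[0] for row in rows]
    b = [row[1] for row in rows]
    return PairedRatings.from_sequences(a, b, categories, drop_missing=True)


def _read_contingency(path: Path, delimiter: str) -> PairedRatings:
    try:
        table = pd.read_csv(path, index_col=0, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise EmptyRatingsError(f"{path} is empty") from None
    table.columns = [str(c).strip() for c in table.columns]
    table.index = [str(i).strip() for i in table.index]
    return ratings_from_contingency(table)


def ratings_from_contingency(table: pd.DataFrame) -> PairedRatings:
    """Expand a square count table (rows: rater A, columns: rater B)."""
    if table.shape[0] != table.shape[1]:
        raise ParseError(
            f"contingency table must be square, got shape {table.shape}"
        )
    row_labels = list(table.index)
    col_labels = list(table.columns)
    if row_labels != col_labels:
        raise ParseError(
            f"row labels {row_labels} do not match column labels {col_labels}"
        )
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts != counts.astype(int)):
        raise ParseError("contingency table entries must be integers")
    counts = counts.astype(int)
    if np.any(counts < 0):
        raise ParseError("contingency table entries must be non-negative")
    if counts.sum() == 0:
        raise EmptyRatingsError("contingency table contains no cases")
    a: list = []
    b: list = []
    for i, la in enumerate(row_labels):
        for j, lb in enumerate(col_labels):
            a.extend([la] * counts[i, j])
            b.extend([lb] * counts[i, j])
    return PairedRatings(tuple(a), tuple(b), tuple(row_labels))


def write_ratings(ratings: PairedRatings, path: str | Path, delimiter: str | None = None) -> None:
    """Write paired ratings as a two-column delimited file with a header."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter_for(path, delimiter))
        writer.writerow(["rater_a", "rater_b"])
        for a, b in zip(ratings.ratings_a, ratings.ratings_b):
            writer.writerow([a, b])


# keep the NA spellings in one place for reuse by callers
NA_VALUES = MISSING_SENTINELS
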