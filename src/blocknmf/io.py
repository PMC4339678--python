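"""Reading and writing expression matrices.

Two on-disk formats are supported, matching common gene-expression exports:

* tab-separated ASCII text, with an optional single header row of column
  (sample) labels and an optional first column of row (gene) labels;
* raw IEEE 754 little-endian binary, row-major, in single or double
  precision, either *headered* (an 8-byte prefix of two little-endian uint32
  giving ``n_rows, n_cols``) or *raw* (no header; the caller supplies the
  dimensions).

Matrices are held in a :class:`LabeledMatrix`: a dense non-negative float
array plus optional row/column label lists.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError, FormatError

__all__ = [
    "LabeledMatrix",
    "read_text",
    "write_text",
    "read_binary",
    "write_binary",
]

_DTYPES = {"single": np.dtype("<f4"), "double": np.dtype("<f8")}


def _element_dtype(precision: str) -> np.dtype:
    try:
        return _DTYPES[precision]
    except KeyError:
        raise ValueError(f"precision must be 'single' or 'double', got {precision!r}")


@dataclass
class LabeledMatrix:
    """A dense non-negative matrix with optional row/column labels.

    Holds the input expression matrix V (genes x samples) and, after a fit,
    the factor matrices W and H. Validation runs at construction: values must
    be a finite, non-negative 2-D array and label lengths must match.
    """

    values: np.ndarray
    row_labels: Optional[list[str]] = None
    col_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise DomainError(
                f"matrix must be 2-D with positive dimensions, got shape {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise DomainError("matrix contains NaN or infinite entries")
        if (self.values < 0).any():
            raise DomainError("non-negative input required")
        n, m = self.values.shape
        if self.row_labels is not None:
            self.row_labels = [str(x) for x in self.row_labels]
            if len(self.row_labels) != n:
                raise DomainError(
                    f"{len(self.row_labels)} row labels for {n} rows"
                )
        if self.col_labels is not None:
            self.col_labels = [str(x) for x in self.col_labels]
            if len(self.col_labels) != m:
                raise DomainError(
                    f"{len(self.col_labels)} column labels for {m} columns"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_text(
    path,
    has_row_labels: Optional[bool] = None,
    has_col_labels: Optional[bool] = None,
) -> LabeledMatrix:
    """Read a tab-separated text matrix.

    When a label flag is ``None`` the layout is auto-detected: a non-numeric
    first row means a header of column labels, a non-numeric first field of
    the first data row means a label column. A corner token in the header
    (above the label column) is tolerated and dropped.
    """
    text = Path(path).read_text()
    lines = text.split("\n")
    while lines and lines[-1].strip() == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    rows = [line.split("\t") for line in lines]

    if has_col_labels is None:
        # Ignore the first field: it may be a row label or a corner token.
        has_col_labels = any(not _is_number(tok) for tok in rows[0][1:])
        if len(rows[0]) == 1:
            has_col_labels = not _is_number(rows[0][0]) and len(rows) > 1
    data_rows = rows[1:] if has_col_labels else rows
    if not data_rows:
        raise FormatError(f"{path}: no data rows")
    if has_row_labels is None:
        has_row_labels = not _is_number(data_rows[0][0])

    width = len(data_rows[0])
    values = np.empty((len(data_rows), width - (1 if has_row_labels else 0)))
    row_labels: Optional[list[str]] = [] if has_row_labels else None
    for r, fields in enumerate(data_rows):
        if len(fields) != width:
            raise FormatError(
                f"{path}: row {r + 1} has {len(fields)} fields, expected {width}"
            )
        if has_row_labels:
            row_labels.append(fields[0])  # type: ignore[union-attr]
            fields = fields[1:]
        for c, tok in enumerate(fields):
            try:
                values[r, c] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: cannot parse {tok!r} at data row {r + 1}, column {c + 1}"
                ) from None

    col_labels: Optional[list[str]] = None
    if has_col_labels:
        header = rows[0]
        if len(header) == values.shape[1] + 1:
            header = header[1:]  # drop corner token above the label column
        if len(header) != values.shape[1]:
            raise FormatError(
                f"{path}: header has {len(header)} labels for {values.shape[1]} columns"
            )
        col_labels = header
    return LabeledMatrix(values, row_labels=row_labels, col_labels=col_labels)


def write_text(matrix: LabeledMatrix, path) -> None:
    """Write a tab-separated text matrix; round-trips through :func:`read_text`."""
    out = []
    if matrix.col_labels is not None:
        header = list(matrix.col_labels)
        if matrix.row_labels is not None:
            header = [""] + header
        out.append("\t".join(header))
    for i, row in enumerate(matrix.values):
        fields = [f"{v:.17g}" for v in row]
        if matrix.row_labels is not None:
            fields = [matrix.row_labels[i]] + fields
        out.append("\t".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


_HEADER_STRUCT = struct.Struct("<II")


def read_binary(
    path,
    n_rows: Optional[int] = None,
    n_cols: Optional[int] = None,
    precision: str = "double",
    header: bool = True,
) -> LabeledMatrix:
    """Read a little-endian IEEE 754 binary matrix (row-major payload).

    With ``header=True`` (the default dialect) the first 8 bytes are two
    little-endian uint32 holding the dimensions; with ``header=False`` the
    caller must pass ``n_rows`` and ``n_cols``.
    """
    dtype = _element_dtype(precision)
    raw = Path(path).read_bytes()
    offset = 0
    if header:
        if len(raw) < _HEADER_STRUCT.size:
            raise FormatError(f"{path}: too short for an 8-byte dimension header")
        n_rows, n_cols = _HEADER_STRUCT.unpack_from(raw)
        offset = _HEADER_STRUCT.size
    elif n_rows is None or n_cols is None:
        raise ValueError("raw binary requires explicit n_rows and n_cols")
    if n_rows < 1 or n_cols < 1:
        raise FormatError(f"{path}: non-positive dimensions ({n_rows}, {n_cols})")
    expected = n_rows * n_cols * dtype.itemsize
    if len(raw) - offset != expected:
        raise FormatError(
            f"{path}: payload is {len(raw) - offset} bytes, expected {expected} "
            f"for {n_rows}x{n_cols} {precision}"
        )
    values = np.frombuffer(raw, dtype=dtype, count=n_rows * n_cols, offset=offset)
    values = values.reshape(n_rows, n_cols).astype(np.float64)
    if not np.isfinite(values).all():
        raise DomainError(f"{path}: NaN or infinite payload")
    if (values < 0).any():
        raise DomainError(f"{path}: non-negative input required")
    return LabeledMatrix(values)


def write_binary(matrix: LabeledMatrix, path, precision: str = "double", header: bool = True) -> None:
    """Write the matrix as row-major little-endian IEEE 754 binary.

    Labels are not stored in this format. Writing a double-precision matrix in
    single precision rounds each entry to the nearest float32.
    """
    dtype = _element_dtype(precision)
    n, m = matrix.shape
    payload = np.ascontiguousarray(matrix.values, dtype=dtype).tobytes()
    with open(path, "wb") as fh:
        if header:
            fh.write(_HEADER_STRUCT.pack(n, m))
        fh.write(payload)
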