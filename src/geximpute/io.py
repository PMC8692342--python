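"""Reading, writing and masking of gene-expression matrices.

Genes are rows and samples are columns throughout.  Missing entries are
held as ``NaN`` inside a float matrix; categorical columns store integer
category codes (index into the column's label list) so that the numeric
machinery can carry them, with equality as the only meaningful comparison.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import FormatError, ParseError

DEFAULT_MISSING_MARKERS = frozenset({"?", "NA", "null", ""})

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass
class ExpressionMatrix:
    """An N-gene x M-sample expression matrix with possibly missing cells.

    Parameters
    ----------
    values
        ``(N, M)`` float array; ``NaN`` marks a missing cell.  Categorical
        columns contain non-negative integer codes.
    gene_ids, sample_ids
        Row and column identifiers.
    attr_kinds
        Per-column kind, each ``"numeric"`` or ``"categorical"``.
    categories
        For each categorical column index, the ordered list of labels the
        integer codes refer to.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    attr_kinds: list[str] = field(default_factory=list)
    categories: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one gene and one sample")
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError("id lengths do not match matrix shape")
        if not self.attr_kinds:
            self.attr_kinds = [NUMERIC] * m
        if len(self.attr_kinds) != m:
            raise ValueError("attr_kinds length does not match sample count")
        if len(set(self.sample_ids)) != m:
            raise ValueError("sample_ids must be unique")
        if len(set(self.gene_ids)) != n:
            warnings.warn(
                "duplicate gene ids present; operations key on row index",
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.gene_ids),
            list(self.sample_ids),
            list(self.attr_kinds),
            {k: list(v) for k, v in self.categories.items()},
        )

    def categorical_columns(self) -> list[int]:
        return [j for j, k in enumerate(self.attr_kinds) if k == CATEGORICAL]


@dataclass
class AvailabilityMask:
    """Boolean availability matrix: ``h[i, j]`` is True iff cell (i, j)
    holds an observed value."""

    h: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


def availability_mask(m: ExpressionMatrix) -> AvailabilityMask:
    """Return the availability mask of ``m`` (True where observed)."""
    return AvailabilityMask(~np.isnan(m.values))


def split_complete_incomplete(
    m: ExpressionMatrix, h: AvailabilityMask
) -> tuple[np.ndarray, np.ndarray]:
    """Partition gene indices into (complete, incomplete).

    A gene is complete iff its whole row is observed.  The two index
    arrays are disjoint and together cover ``range(N)``.
    """
    if h.shape != m.shape:
        raise ValueError("mask shape does not match matrix shape")
    row_complete = h.h.all(axis=1)
    idx = np.arange(m.n_genes)
    return idx[row_complete], idx[~row_complete]


def _parse_cell(
    text: str,
    missing_markers: frozenset[str] | set[str],
    kind: str,
    catalog: dict[str, int],
    labels: list[str],
    line_no: int,
    col_name: str,
) -> float:
    stripped = text.strip()
    if stripped in missing_markers:
        return np.nan
    if kind == CATEGORICAL:
        code = catalog.get(stripped)
        if code is None:
            code = len(labels)
            catalog[stripped] = code
            labels.append(stripped)
        return float(code)
    try:
        value = float(stripped)
    except ValueError as exc:
        raise ParseError(
            f"line {line_no}: cell in column '{col_name}' is neither numeric "
            f"nor a missing marker: {stripped!r}"
        ) from exc
    if not np.isfinite(value):
        raise ParseError(
            f"line {line_no}: non-finite numeric cell in column '{col_name}': "
            f"{stripped!r}"
        )
    return value


def read_matrix(
    path,
    missing_markers: set[str] | frozenset[str] = DEFAULT_MISSING_MARKERS,
    delimiter: str = "\t",
    header: bool = True,
    categorical_columns: set[str] | set[int] | None = None,
) -> ExpressionMatrix:
    """Read a delimited gene-expression table.

    Layout: first column is the gene id; an optional header row carries
    sample ids.  Cells matching any entry of ``missing_markers`` become
    missing.  ``categorical_columns`` may name samples (by header id or
    0-based column index) whose cells are category labels rather than
    numbers.

    Raises
    ------
    ParseError
        On a row whose field count disagrees with the header, or an
        unparseable numeric cell, naming the offending line.
    """
    missing_markers = frozenset(missing_markers)
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for row in reader:
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: file is empty")

    if header:
        sample_ids = [c.strip() for c in rows[0][1:]]
        data_rows = rows[1:]
        first_line = 2
    else:
        sample_ids = [f"s{j + 1}" for j in range(len(rows[0]) - 1)]
        data_rows = rows
        first_line = 1
    if not data_rows:
        raise ParseError(f"{path}: no data rows")

    m = len(sample_ids)
    cat_idx: set[int] = set()
    if categorical_columns:
        for c in categorical_columns:
            if isinstance(c, int):
                cat_idx.add(c)
            else:
                cat_idx.add(sample_ids.index(c))
    attr_kinds = [CATEGORICAL if j in cat_idx else NUMERIC for j in range(m)]
    catalogs: dict[int, dict[str, int]] = {j: {} for j in cat_idx}
    labels: dict[int, list[str]] = {j: [] for j in cat_idx}

    gene_ids: list[str] = []
    values = np.empty((len(data_rows), m), dtype=float)
    for r, row in enumerate(data_rows):
        line_no = first_line + r
        if len(row) != m + 1:
            raise ParseError(
                f"line {line_no}: expected {m + 1} fields "
                f"(id + {m} samples), found {len(row)}"
            )
        gene_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            values[r, j] = _parse_cell(
                cell,
                missing_markers,
                attr_kinds[j],
                catalogs.get(j, {}),
                labels.get(j, []),
                line_no,
                sample_ids[j],
            )
    return ExpressionMatrix(values, gene_ids, sample_ids, attr_kinds, labels)


def write_matrix(
    m: ExpressionMatrix,
    path,
    delimiter: str = "\t",
    missing_marker: str = "?",
) -> None:
    """Write a matrix as delimited text; ``repr`` of floats round-trips
    bit-for-bit through :func:`read_matrix`."""
    cat_cols = set(m.categorical_columns())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["gene_id", *m.sample_ids])
        for i, gid in enumerate(m.gene_ids):
            row: list[str] = [gid]
            for j in range(m.n_samples):
                v = m.values[i, j]
                if np.isnan(v):
                    row.append(missing_marker)
                elif j in cat_cols:
                    row.append(m.categories[j][int(v)])
                else:
                    row.append(repr(float(v)))
            writer.writerow(row)


def read_gds_soft(path) -> ExpressionMatrix:
    """Parse the dataset value table of a GEO GDS SOFT file.

    Only the block between ``!dataset_table_begin`` and
    ``!dataset_table_end`` is consumed.  Rows are probes (keyed by
    ``ID_REF``); columns are the GSM sample columns.  ``null`` and empty
    cells become missing.

    Raises
    ------
    FormatError
        If the table delimiters are absent.
    """
    in_table = False
    header: list[str] | None = None
    gene_ids: list[str] = []
    data: list[list[float]] = []
    sample_cols: list[int] = []
    sample_ids: list[str] = []
    saw_end = False
    markers = frozenset({"null", "NULL", "", "?", "NA"})

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line.startswith("!dataset_table_begin"):
                in_table = True
                continue
            if line.startswith("!dataset_table_end"):
                saw_end = True
                break
            if not in_table:
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for j, name in enumerate(fields):
                    if name.startswith("GSM"):
                        sample_cols.append(j)
                        sample_ids.append(name)
                if not sample_cols:
                    raise FormatError(
                        f"{path}: dataset table has no GSM sample columns"
                    )
                continue
            if not line:
                continue
            gene_ids.append(fields[0])
            row = []
            for j in sample_cols:
                cell = fields[j].strip() if j < len(fields) else ""
                if cell in markers:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path} line {line_no}: unparseable value "
                            f"{cell!r} in column {header[j]}"
                        ) from exc
            data.append(row)

    if header is None or not saw_end:
        raise FormatError(
            f"{path}: missing !dataset_table_begin/!dataset_table_end block"
        )
    if not data:
        raise FormatError(f"{path}: dataset table contains no data rows")
    return ExpressionMatrix(np.array(data, dtype=float), gene_ids, sample_ids)
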