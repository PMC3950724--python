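"""Read, validate and write tab-delimited expression matrices.

The on-disk dialect is the common compendium layout: a header row whose
first cell is an arbitrary label and whose remaining cells are chip
(sample) names, followed by one row per gene of ``gene_id`` and ``m``
numeric expression values.  Files may be gzip-compressed (``.gz``
extension).  Values are assumed already normalized upstream; no
transformation is applied on load.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ExpressionFormatError",
    "ExpressionValidationError",
    "read_expression",
    "write_expression",
]


class ExpressionFormatError(ValueError):
    """A cell or row of the input file could not be parsed."""


class ExpressionValidationError(ValueError):
    """The matrix violates a structural invariant (ids, shape, finiteness)."""


def _check_identifier(kind: str, ident: str) -> None:
    if not ident:
        raise ExpressionValidationError(f"empty {kind} identifier")
    if "\t" in ident or "\n" in ident or "\r" in ident:
        raise ExpressionValidationError(
            f"{kind} identifier {ident!r} contains a tab or newline; "
            "not representable in the tab-delimited dialect"
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique row/column identifiers.

    Parameters
    ----------
    gene_ids:
        Row identifiers (probe-set IDs or gene names), unique, order
        preserved from the source.
    sample_ids:
        Chip names, unique.  Chips are the unit of "condition" in the
        condition-removal test, so ambiguity is rejected here.
    values:
        Float matrix of shape ``(len(gene_ids), len(sample_ids))``; every
        entry must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ExpressionValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ExpressionValidationError(
                f"{len(self.gene_ids)} gene ids for {n} rows"
            )
        if len(self.sample_ids) != m:
            raise ExpressionValidationError(
                f"{len(self.sample_ids)} sample ids for {m} columns"
            )
        if n < 2:
            raise ExpressionValidationError(f"need at least 2 genes, got {n}")
        if m < 3:
            raise ExpressionValidationError(f"need at least 3 samples, got {m}")
        for g in self.gene_ids:
            _check_identifier("gene", g)
        for s in self.sample_ids:
            _check_identifier("sample", s)
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ExpressionValidationError(f"duplicate gene id {g!r}")
            seen.add(g)
        seen.clear()
        for s in self.sample_ids:
            if s in seen:
                raise ExpressionValidationError(f"duplicate sample id {s!r}")
            seen.add(s)
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n(self) -> int:
        """Number of genes (rows)."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of samples/chips (columns)."""
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector for one gene across all samples."""
        return self.values[self.gene_index(gene_id)]


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"), encoding="utf-8")
    # newline="" keeps universal-newline translation for reads and gives
    # explicit "\n" control for writes
    return open(path, mode, encoding="utf-8", newline="" if "w" in mode else None)


def read_expression(path) -> ExpressionMatrix:
    """Parse a tab-delimited expression file into an :class:`ExpressionMatrix`.

    The first header cell is ignored; the rest are chip names.  Raises
    :class:`ExpressionFormatError` with the offending line number for rows
    with the wrong field count or non-numeric cells, and
    :class:`ExpressionValidationError` for structural problems (duplicate
    ids, too few samples, etc.).
    """
    with _open_text(path, "r") as fh:
        header = fh.readline()
        if not header:
            raise ExpressionFormatError(f"{path}: empty file")
        header_fields = header.rstrip("\r\n").split("\t")
        if len(header_fields) < 2:
            raise ExpressionFormatError(f"{path}: header has no sample columns")
        sample_ids = header_fields[1:]
        m = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != m + 1:
                raise ExpressionFormatError(
                    f"{path}:{lineno}: expected {m + 1} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append(np.array([float(v) for v in fields[1:]]))
            except ValueError:
                for col, v in enumerate(fields[1:], start=1):
                    try:
                        float(v)
                    except ValueError:
                        raise ExpressionFormatError(
                            f"{path}:{lineno}: non-numeric value {v!r} in "
                            f"column {col + 1} (sample {sample_ids[col - 1]!r})"
                        ) from None
                raise
    if not gene_ids:
        raise ExpressionFormatError(f"{path}: no data rows")
    values = np.vstack(rows)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ExpressionFormatError(
            f"{path}: non-finite value for gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)


def write_expression(matrix: ExpressionMatrix, path, *, label: str = "id"):
    """Write ``matrix`` in the tab-delimited dialect read by :func:`read_expression`.

    Values are rendered with ``repr`` so a read/write round trip is exact.
    Returns ``path``.
    """
    if not isinstance(matrix, ExpressionMatrix):
        matrix = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, matrix.values)
    with _open_text(path, "w") as fh:
        fh.write(label + "\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path
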