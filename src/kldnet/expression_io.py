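"""Reading, validation and alignment of expression matrices, sample labels and biotype maps.

The canonical in-memory orientation is genes x samples: rows are genes,
columns are samples, and column ``j`` of :class:`LabelledDataset` is the
sample whose label is ``labels.y[j]``. The reader handles transposition so
downstream code never has to guess the orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kldnet.expression_io")

PROTEIN_CODING = "protein_coding"

#: gene_id -> biotype string; genes absent from the map count as non-coding
BiotypeMap = dict[str, str]

#: label tokens accepted by :func:`read_labels`, mapped to {0, 1}
LABEL_TOKENS = {"0": 0, "1": 1, "normal": 0, "tumor": 1}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A gene x sample matrix of non-negative expression counts.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``. Counts may be any non-negative reals: level-3
    repository files sometimes contain normalized, non-integer values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleLabels:
    """Binary sample labels: 1 = tumor (diseased), 0 = normal."""

    sample_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=int)
        if self.y.ndim != 1 or len(self.y) != len(self.sample_ids):
            raise DataError("labels must be a vector aligned with sample_ids")
        _check_unique(self.sample_ids, "sample")
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise DataError(f"labels must be 0/1, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class LabelledDataset:
    """An expression matrix aligned with its sample labels.

    Column ``j`` of ``matrix.values`` belongs to the sample with label
    ``labels.y[j]``. ``provenance`` records how the join was performed.
    """

    matrix: ExpressionMatrix
    labels: SampleLabels
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.matrix.sample_ids != self.labels.sample_ids:
            raise DataError("matrix and labels sample order differ; use assemble_dataset")

    @property
    def y(self) -> np.ndarray:
        return self.labels.y

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    # auto-detection limited to tab and comma; explicit flag overrides
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_in_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into canonical genes x samples form.

    The first row holds identifiers for the non-leading axis and the first
    column identifiers for the leading axis. ``orientation`` says which axis
    is in rows in the *file*; the returned matrix is always genes x samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as e:
        raise DataError(f"ragged or malformed table in {path}: {e}") from e
    if df.empty:
        raise DataError(f"no data rows in {path}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        dupes = list(df.index[df.index.duplicated()]) + list(df.columns[df.columns.duplicated()])
        raise DataError(f"duplicate identifiers in {path}: {dupes[:5]}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise DataError(f"non-numeric values in column(s) {list(non_numeric)[:5]} of {path}")
    if orientation == "samples_in_rows":
        df = df.T
    m = ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))
    logger.info("read %d genes x %d samples from %s", m.n_genes, m.n_samples, path)
    return m


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a matrix in the canonical layout (genes in rows). Round-trips
    bit-identically with :func:`read_expression_matrix` for finite decimal input."""
    path = Path(path)
    m.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")
    return path


def read_labels(path: str | Path) -> SampleLabels:
    """Read a two-column sample_id / label table.

    Accepted label tokens (case-insensitive): 0, 1, normal, tumor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label table not found: {path}")
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataError(f"no samples in {path}") from None
    # tolerate an optional header line
    if len(df) and str(df.iloc[0, 0]).lower() in ("sample_id", "sample", "id"):
        df = df.iloc[1:]
    if df.empty:
        raise DataError(f"no samples in {path}")
    if df.shape[1] < 2:
        raise DataError(f"label table {path} needs two columns: sample_id, label")
    ids = [str(s).strip() for s in df.iloc[:, 0]]
    y = []
    for sid, tok in zip(ids, df.iloc[:, 1]):
        key = str(tok).strip().lower()
        if key not in LABEL_TOKENS:
            raise DataError(
                f"unknown label {tok!r} for sample {sid!r}; "
                f"accepted tokens: {sorted(LABEL_TOKENS)}"
            )
        y.append(LABEL_TOKENS[key])
    labels = SampleLabels(ids, np.array(y))
    logger.info(
        "read %d samples (%d tumor, %d normal) from %s",
        labels.n_samples, int(labels.y.sum()), int((1 - labels.y).sum()), path,
    )
    return labels


def read_biotype_map(path: str | Path) -> dict[str, str]:
    """Read a two-column gene_id / biotype table (e.g. extracted from a GTF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"biotype map not found: {path}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataError(f"biotype map {path} needs two columns: gene_id, biotype")
    return {str(g).strip(): str(b).strip() for g, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def filter_protein_coding(m: ExpressionMatrix, biotypes: Mapping[str, str]) -> ExpressionMatrix:
    """Keep genes whose biotype is protein_coding, preserving row order.

    Genes absent from the map are treated as non-coding and dropped.
    """
    keep = [i for i, g in enumerate(m.gene_ids) if biotypes.get(g) == PROTEIN_CODING]
    if not keep:
        raise DataError("protein-coding filter removed every gene")
    removed = m.n_genes - len(keep)
    if removed:
        logger.info("protein-coding filter: kept %d genes, removed %d", len(keep), removed)
    if removed == 0:
        return m
    return ExpressionMatrix(
        [m.gene_ids[i] for i in keep], list(m.sample_ids), m.values[keep, :]
    )


def assemble_dataset(
    m: ExpressionMatrix, labels: SampleLabels, join: str = "strict"
) -> LabelledDataset:
    """Align matrix columns to label order.

    ``strict`` requires identical sample-id sets; ``intersect`` keeps the
    labelled samples present in the matrix and records how many were dropped.
    """
    if join not in ("strict", "intersect"):
        raise ValueError(f"unknown join {join!r}")
    matrix_ids = set(m.sample_ids)
    label_ids = set(labels.sample_ids)
    if join == "strict":
        if matrix_ids != label_ids:
            only_m = sorted(matrix_ids - label_ids)[:5]
            only_l = sorted(label_ids - matrix_ids)[:5]
            raise DataError(
                f"strict join: sample sets differ (matrix-only {only_m}, labels-only {only_l})"
            )
        kept = list(labels.sample_ids)
        note = "strict join"
        lab = labels
    else:
        kept = [s for s in labels.sample_ids if s in matrix_ids]
        if not kept:
            raise DataError("intersection of matrix and label samples is empty")
        dropped = (m.n_samples - len(kept)) + (labels.n_samples - len(kept))
        note = f"intersect join: kept {len(kept)} samples, dropped {dropped}"
        logger.info("%s", note)
        keep_mask = [s in matrix_ids for s in labels.sample_ids]
        lab = SampleLabels(kept, labels.y[np.array(keep_mask)])
    col = {s: j for j, s in enumerate(m.sample_ids)}
    order = [col[s] for s in kept]
    aligned = ExpressionMatrix(list(m.gene_ids), kept, m.values[:, order])
    return LabelledDataset(aligned, lab, provenance=note)
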