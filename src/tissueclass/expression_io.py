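"""Reading, validating and aggregating FPKM expression matrices.

The raw unit of data is a gene x sample matrix of non-negative FPKM values
(:class:`SampleMatrix`) together with a manifest mapping each sample to a
tissue (:class:`SampleManifest`).  Replicate samples are collapsed to one
column per tissue by arithmetic mean (:func:`aggregate_to_tissue`), producing
the gene x tissue :class:`ExpressionMatrix` the classifier consumes.

Matrices are dense by construction (an expression atlas reports a value for
every gene in every sample), so missing values are rejected rather than
imputed.  Gene identifiers are opaque strings; an optional ``normalize_gene_id``
hook can be passed to :func:`read_matrix` (e.g. to strip Ensembl versions) but
no normalization happens by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MappingError, MatrixValueError

__all__ = [
    "SampleMatrix",
    "SampleManifest",
    "ExpressionMatrix",
    "read_matrix",
    "read_manifest",
    "aggregate_to_tissue",
    "write_matrix",
    "write_manifest",
    "write_table",
]


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {kind} identifier(s): {', '.join(map(str, dupes[:5]))}")


def _check_values(values: pd.DataFrame, row_kind: str, col_kind: str) -> None:
    arr = values.to_numpy()
    if arr.size == 0:
        raise FormatError("empty expression matrix")
    if not np.issubdtype(arr.dtype, np.number):
        bad = values.columns[values.apply(lambda c: not pd.api.types.is_numeric_dtype(c))]
        raise MatrixValueError(f"non-numeric values in {col_kind}(s): {', '.join(map(str, bad[:5]))}")
    mask = ~np.isfinite(arr) | (arr < 0)
    if mask.any():
        i, j = np.argwhere(mask)[0]
        raise MatrixValueError(
            f"invalid value {arr[i, j]!r} for gene {values.index[i]!r} in "
            f"{col_kind} {values.columns[j]!r} (values must be finite and non-negative)"
        )


@dataclass
class SampleMatrix:
    """Gene x sample FPKM matrix (replicate level).

    ``values`` is a DataFrame indexed by gene id with one column per sample id.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float, copy=False)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        _check_values(self.values, "gene", "sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleManifest:
    """Mapping of sample id -> tissue label."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(isinstance(t, str) and t for t in self.entries.values()):
            raise FormatError("every manifest entry needs a non-empty tissue label")

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def samples_for(self, tissue: str) -> list[str]:
        return [s for s, t in self.entries.items() if t == tissue]


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM matrix (replicates collapsed to the tissue mean)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float, copy=False)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "tissue")
        _check_values(self.values, "gene", "tissue")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]


def read_matrix(
    path: str | Path,
    normalize_gene_id: Callable[[str], str] | None = None,
) -> SampleMatrix:
    """Read a TSV expression matrix (``gene_id<TAB>sample1<TAB>...``).

    Row and column order of the file are preserved.  Raises
    :class:`FormatError` for structural problems (duplicate identifiers, empty
    matrix) and :class:`MatrixValueError` for negative or non-numeric cells,
    naming the offending gene and sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a gene-id column plus at least one sample column")
    # pandas mangles duplicate column names, so check the raw header line
    with open(path, encoding="utf-8") as fh:
        headers = fh.readline().rstrip("\r\n").split("\t")
    _check_unique(headers[1:], "sample")
    genes = df.iloc[:, 0].astype(str)
    if normalize_gene_id is not None:
        genes = genes.map(normalize_gene_id)
    body = df.iloc[:, 1:].copy()
    body.columns = headers[1:]
    body.index = pd.Index(genes, name=headers[0])
    for col in body.columns:
        try:
            body[col] = pd.to_numeric(body[col])
        except (ValueError, TypeError) as exc:
            raise MatrixValueError(f"{path}: non-numeric value in sample column {col!r}: {exc}") from exc
    return SampleMatrix(body)


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest TSV (``sample_id<TAB>tissue``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: manifest needs sample_id and tissue columns")
    samples = df.iloc[:, 0].astype(str)
    _check_unique(samples, "sample")
    tissues = df.iloc[:, 1].astype(str)
    return SampleManifest(dict(zip(samples, tissues)))


def aggregate_to_tissue(m: SampleMatrix, manifest: SampleManifest) -> ExpressionMatrix:
    """Collapse replicate samples to per-tissue arithmetic means.

    Every sample column of ``m`` must be assigned to a tissue in ``manifest``;
    manifest entries for samples absent from the matrix are ignored with a
    warning.  Output tissues are ordered lexicographically so downstream
    results are deterministic.
    """
    missing = [s for s in m.sample_ids if s not in manifest.entries]
    if missing:
        raise MappingError(f"sample(s) missing from manifest: {', '.join(missing[:5])}")
    extra = [s for s in manifest.entries if s not in set(m.sample_ids)]
    if extra:
        warnings.warn(
            f"{len(extra)} manifest sample(s) absent from the matrix were ignored",
            stacklevel=2,
        )
    groups = pd.Series({s: manifest.entries[s] for s in m.sample_ids})
    agg = m.values.T.groupby(groups).mean().T
    agg = agg.reindex(columns=sorted(agg.columns))
    agg.columns.name = "tissue"
    return ExpressionMatrix(agg)


def write_matrix(m: SampleMatrix | ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix back to TSV, preserving full float precision."""
    m.values.to_csv(Path(path), sep="\t", index_label=m.values.index.name or "gene_id")


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(manifest.entries), "tissue": list(manifest.entries.values())}
    )
    df.to_csv(Path(path), sep="\t", index=False)


def write_table(rows: Sequence[Mapping[str, object]] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular records to TSV: header row, floats with 4 decimals, rows as given.

    An empty record list still needs a schema, so pass a DataFrame with columns
    when there are no rows.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and not all(set(r.keys()) == set(rows[0].keys()) for r in rows):
            raise FormatError("records do not share a schema")
        df = pd.DataFrame(rows)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.4f")
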