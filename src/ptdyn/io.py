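"""Readers and writers for the pipeline's on-disk currencies.

Expression matrices travel as pandas DataFrames with genes in rows and
cells in columns (FPKM-like, non-negative). Two disk layouts are
supported: a plain TSV (first column = gene symbol, header row = cell
ids) and a MatrixMarket triplet accompanied by ``genes.tsv`` /
``barcodes.tsv`` name files. Gene sets travel in GMT format.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MatrixFormatError(ValueError):
    """Raised when a matrix violates the expression-matrix contract."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the genes x cells contract: unique names, no negatives.

    Returns the matrix unchanged so calls can be inlined.
    """
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise MatrixFormatError(f"duplicate gene identifier: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise MatrixFormatError(f"duplicate cell identifier: {dup!r}")
    values = matrix.to_numpy()
    if not np.isfinite(values).all():
        raise MatrixFormatError("matrix contains non-finite values")
    if (values < 0).any():
        raise MatrixFormatError("matrix contains negative expression values")
    return matrix


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x cells TSV (first column gene ids, header cell ids)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return validate_matrix(matrix)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | os.PathLike,
                     float_format: str = "%.6g") -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format=float_format)


def read_matrix_mtx(mtx_path: str | os.PathLike,
                    genes_path: str | os.PathLike,
                    barcodes_path: str | os.PathLike) -> pd.DataFrame:
    """Read a MatrixMarket triplet with sidecar gene / cell name files."""
    values = scipy.io.mmread(os.fspath(mtx_path))
    if scipy.sparse.issparse(values):
        values = values.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    matrix = pd.DataFrame(np.asarray(values), index=genes, columns=cells)
    return validate_matrix(matrix)


def write_matrix_mtx(matrix: pd.DataFrame, out_dir: str | os.PathLike,
                     prefix: str = "matrix") -> None:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.to_numpy())
    scipy.io.mmwrite(os.path.join(out_dir, f"{prefix}.mtx"), sparse)
    pd.Series(matrix.index).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", header=False, index=False)
    pd.Series(matrix.columns).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. functional signatures loaded from a GMT file.

    ``sets`` maps a unique set name to its member gene symbols
    (case-sensitive); ``source`` records provenance free-text.
    """

    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line (need name, description, >=1 member): {line!r}")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"duplicate gene set name in GMT: {name!r}")
            members = [g for g in fields[2:] if g]
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets=sets, source=os.fspath(path),
                             descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for name, members in collection.sets.items():
            description = collection.descriptions.get(name, "na")
            handle.write("\t".join([name, description, *members]) + "\n")


def read_pseudotime_tsv(path: str | os.PathLike) -> pd.Series:
    """Read a two-column (cell_id, pt) TSV into a Series indexed by cell."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("pseudotime TSV needs columns (cell_id, pt)")
    series = pd.Series(table.iloc[:, 1].to_numpy(float),
                       index=table.iloc[:, 0].astype(str), name="pt")
    return series


def write_pseudotime_tsv(pt: pd.Series, path: str | os.PathLike) -> None:
    frame = pd.DataFrame({"cell_id": pt.index, "pt": pt.to_numpy()})
    frame.to_csv(path, sep="\t", index=False, float_format="%.8f")


def write_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
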