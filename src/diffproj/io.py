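"""Reading and writing single-cell exchange formats.

The on-disk interchange formats are the 10x-style Matrix Market directory
(``matrix.mtx[.gz]`` plus ``barcodes.tsv[.gz]`` and ``features.tsv[.gz]`` /
``genes.tsv[.gz]``), dense TSV count tables, and plain-text gene-set files.
Internally cells are always rows; the 10x genes-by-cells orientation is
transposed on read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class InputError(ValueError):
    """A required input file is missing or unreadable."""


class ValidationError(ValueError):
    """An input violates a structural contract."""


@dataclass
class CountMatrix:
    """Sparse nonnegative integer cell-by-gene count matrix.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Counts, cells as rows, genes as columns.
    barcodes : np.ndarray of str
        Unique per-cell identifiers, length ``values.shape[0]``.
    features : pd.DataFrame
        Columns ``id`` and ``symbol``; ids unique, length ``values.shape[1]``.
    sample_of : np.ndarray of str or None
        Optional per-cell sample tag.
    """

    values: sp.csr_matrix
    barcodes: np.ndarray
    features: pd.DataFrame
    sample_of: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not {"id", "symbol"}.issubset(self.features.columns):
            raise ValidationError("features must have 'id' and 'symbol' columns")
        n, g = self.values.shape
        if len(self.barcodes) != n:
            raise ValidationError(
                f"barcode count {len(self.barcodes)} != cell count {n}"
            )
        if len(self.features) != g:
            raise ValidationError(
                f"feature count {len(self.features)} != gene count {g}"
            )
        if len(np.unique(self.barcodes)) != n:
            raise ValidationError("duplicate barcodes")
        if self.features["id"].duplicated().any():
            raise ValidationError("duplicate feature ids")
        data = self.values.data
        if data.size:
            if np.issubdtype(data.dtype, np.floating):
                if not np.allclose(data, np.round(data)):
                    raise ValidationError("counts must be integral")
                self.values = self.values.astype(np.int64)
            if self.values.data.min(initial=0) < 0:
                raise ValidationError("counts must be nonnegative")
        self.values = self.values.astype(np.int64)
        self.values.eliminate_zeros()
        if self.sample_of is not None:
            self.sample_of = np.asarray(self.sample_of, dtype=object)
            if len(self.sample_of) != n:
                raise ValidationError("sample_of length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def symbols(self) -> np.ndarray:
        return self.features["symbol"].to_numpy(dtype=object)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a copy restricted to the cells selected by ``mask``."""
        mask = np.asarray(mask)
        return CountMatrix(
            values=self.values[mask],
            barcodes=self.barcodes[mask],
            features=self.features.reset_index(drop=True),
            sample_of=None if self.sample_of is None else self.sample_of[mask],
        )


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.is_file():
                return cand
    raise InputError(
        f"none of {stems} (optionally .gz) found in {directory}"
    )


def _read_tsv_lines(path: Path) -> list[list[str]]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_mtx_dir(path: str | Path) -> CountMatrix:
    """Read a 10x-style Matrix Market directory into a :class:`CountMatrix`.

    The matrix may be stored genes-by-cells (the 10x convention) or
    cells-by-genes; orientation is detected by matching dimensions against
    the barcode and feature lists and the result always has cells as rows.
    Feature files with 1, 2 or 3+ columns are accepted (id; id+symbol;
    id+symbol+type); the symbol defaults to the id. Explicit zeros are
    dropped. A square matrix is assumed to be genes-by-cells.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    mtx_path = _find_file(directory, ["matrix.mtx"])
    bc_path = _find_file(directory, ["barcodes.tsv"])
    ft_path = _find_file(directory, ["features.tsv", "genes.tsv"])

    barcodes = np.array([row[0] for row in _read_tsv_lines(bc_path)], dtype=object)
    ft_rows = _read_tsv_lines(ft_path)
    ids = [row[0] for row in ft_rows]
    symbols = [row[1] if len(row) > 1 else row[0] for row in ft_rows]
    features = pd.DataFrame({"id": ids, "symbol": symbols})

    with _open_maybe_gz(mtx_path, "rt") as fh:
        mat = mmread(fh)
    mat = sp.coo_matrix(mat)
    if mat.data.size and np.issubdtype(mat.data.dtype, np.floating):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValidationError(f"non-integer values in {mtx_path}")
        mat = mat.astype(np.int64)

    n_bc, n_ft = len(barcodes), len(features)
    if mat.shape == (n_ft, n_bc):
        mat = mat.T  # genes x cells on disk
    elif mat.shape != (n_bc, n_ft):
        raise ValidationError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={n_bc}, genes={n_ft}) nor its transpose"
        )
    return CountMatrix(values=mat.tocsr(), barcodes=barcodes, features=features)


def write_mtx_dir(matrix: CountMatrix, path: str | Path) -> None:
    """Write ``matrix`` as a Matrix Market directory readable by :func:`read_mtx_dir`.

    The matrix is stored genes-by-cells with an integer field, following the
    10x convention.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(
        str(directory / "matrix.mtx"),
        sp.coo_matrix(matrix.values.T),
        field="integer",
    )
    with open(directory / "barcodes.tsv", "w") as fh:
        for bc in matrix.barcodes:
            fh.write(f"{bc}\n")
    with open(directory / "features.tsv", "w") as fh:
        for _, row in matrix.features.iterrows():
            fh.write(f"{row['id']}\t{row['symbol']}\tGene Expression\n")


def read_gene_set(path: str | Path) -> list[str]:
    """Read a gene-set file: one symbol per line, ``#`` comments allowed.

    Returns de-duplicated symbols in file order, case preserved.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    p = Path(path)
    if not p.is_file():
        raise InputError(f"gene-set file not found: {p}")
    with _open_maybe_gz(p) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token and token not in seen:
                seen.add(token)
                symbols.append(token)
    if not symbols:
        raise ValidationError(f"gene-set file {p} contains no symbols")
    return symbols


def read_dense_counts(path: str | Path) -> CountMatrix:
    """Read a dense TSV count table (header of gene symbols, first column barcodes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValidationError("non-integer values in dense count table")
    features = pd.DataFrame({"id": df.columns, "symbol": df.columns})
    return CountMatrix(
        values=sp.csr_matrix(values.astype(np.int64)),
        barcodes=df.index.to_numpy(dtype=object),
        features=features,
    )


def read_counts(path: str | Path) -> CountMatrix:
    """Dispatch on ``path``: directory -> MTX directory, file -> dense TSV."""
    p = Path(path)
    if p.is_dir():
        return read_mtx_dir(p)
    if p.is_file():
        return read_dense_counts(p)
    raise InputError(f"no such file or directory: {p}")
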