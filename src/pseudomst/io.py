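"""Expression-matrix data model and file I/O.

The in-memory container is :class:`ExpressionMatrix`: a dense genes x cells
float matrix with unique gene and cell identifiers, optionally carrying a
per-cell collection-time label (the time point each cell was harvested at,
used only for evaluation, never for ordering).

Supported on-disk formats:

* dense TSV/CSV — first column gene id, header row of cell ids;
* Matrix Market coordinate triplets (``.mtx``) with companion one-name-per-line
  gene and cell files;
* a two-column (cell_id, time_label) TSV for collection times.

All downstream computation uses the matrix exactly as loaded (apart from the
optional log transform); the pipeline never re-normalizes library sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def _check_unique(names: list[str], what: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {what} identifier: {n!r}")
        seen.add(n)


@dataclass
class ExpressionMatrix:
    """Dense genes x cells expression matrix.

    Parameters
    ----------
    values
        ``(G, N)`` float array; every entry finite.
    gene_ids, cell_ids
        Unique row / column identifiers.
    collection_time
        Optional length-``N`` array of per-cell collection-time labels
        (ordinal; raw hours or time-point indices both work).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    collection_time: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if self.collection_time is not None:
            self.collection_time = np.asarray(self.collection_time)
            if self.collection_time.shape != (n,):
                raise ValueError(
                    f"collection_time has length {len(self.collection_time)}, "
                    f"expected {n}"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, indices: np.ndarray) -> "ExpressionMatrix":
        """Column subset preserving original cell order of `indices`."""
        idx = np.asarray(indices, dtype=int)
        ct = None if self.collection_time is None else self.collection_time[idx]
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            collection_time=ct,
        )

    def subset_genes(self, indices: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[idx, :].copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            collection_time=None
            if self.collection_time is None
            else self.collection_time.copy(),
        )

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None


def _companion_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def load_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Load a genes x cells matrix from TSV, CSV or Matrix Market triplets.

    ``format`` is one of ``{"tsv", "csv", "mtx-triplet"}``; when ``None`` it is
    inferred from the file suffix.  Matrix Market input expects companion
    ``<stem>.genes.txt`` / ``<stem>.cells.txt`` name files next to the
    ``.mtx`` file, one identifier per line; unlisted entries are dense zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")

    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split(sep)
        cell_ids = header[1:]
        _check_unique(cell_ids, "cell")
        df = pd.read_csv(
            path, sep=sep, index_col=0, header=0, float_precision="round_trip"
        )
        gene_ids = [str(g) for g in df.index]
        _check_unique(gene_ids, "gene")
        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(converted.isna().to_numpy())
            if bad.size:
                raise ValueError(
                    f"non-numeric entry at gene {gene_ids[bad[0]]!r}, "
                    f"cell {cell_ids[j]!r}"
                )
            values[:, j] = converted.to_numpy(dtype=float)
        return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)

    if format == "mtx-triplet":
        genes_path, cells_path = _companion_paths(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"companion name file missing: {p}")
        gene_ids = genes_path.read_text(encoding="utf-8").split()
        cell_ids = cells_path.read_text(encoding="utf-8").split()
        _check_unique(gene_ids, "gene")
        _check_unique(cell_ids, "cell")
        mat = scipy.io.mmread(path)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells in name files"
            )
        return ExpressionMatrix(values=dense, gene_ids=gene_ids, cell_ids=cell_ids)

    raise ValueError(f"unknown format: {format!r}")


def write_expression(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix in TSV, CSV, or Matrix Market triplet form."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
        df.to_csv(path, sep=sep, index_label="gene_id")
    elif format == "mtx-triplet":
        genes_path, cells_path = _companion_paths(path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        genes_path.write_text("\n".join(m.gene_ids) + "\n", encoding="utf-8")
        cells_path.write_text("\n".join(m.cell_ids) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format: {format!r}")


def load_collection_time(path: str | Path, m: ExpressionMatrix) -> ExpressionMatrix:
    """Attach collection-time labels from a (cell_id, time_label) TSV.

    Every cell of ``m`` must appear in the file; extra rows are ignored.
    Numeric labels are kept numeric so that ordering by raw time works.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("collection-time file needs columns (cell_id, time_label)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [c for c in m.cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"cells without a time label: {missing[:5]}")
    labels = np.asarray([mapping[c] for c in m.cell_ids])
    return replace(m, collection_time=labels)


def log_transform(
    m: ExpressionMatrix, pseudocount: float = 1.0, base: float = 2.0
) -> ExpressionMatrix:
    """Replace every entry ``y`` with ``log_base(y + pseudocount)``.

    Expression units such as TPM/FPKM are non-negative; a negative input
    signals data that were already log-scaled (or corrupted) and is rejected.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if np.any(m.values < 0):
        g, c = np.argwhere(m.values < 0)[0]
        raise ValueError(
            f"negative value at gene {m.gene_ids[g]!r}, cell {m.cell_ids[c]!r}: "
            "input looks already log-scaled or corrupt"
        )
    vals = np.log(m.values + pseudocount) / math.log(base)
    return replace(m, values=vals)
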