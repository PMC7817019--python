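"""Readers and writers for the supported on-disk formats.

Three matrix formats round-trip losslessly:

* Matrix Market (``.mtx``) with companion one-column label TSVs
  (``<stem>_barcodes.tsv`` for cells, ``<stem>_genes.tsv`` for genes);
* dense CSV/TSV with a header row of gene labels and a first column of
  cell labels;
* HDF5 with ``/X`` (dense dataset or CSR group ``data/indices/indptr/
  shape``), ``/obs_names`` and ``/var_names``.

Matrices are stored cells x genes.  A Matrix Market file whose label
sidecars indicate genes x cells orientation is transposed on read with
a logged notice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_graph_triplets",
    "write_graph_triplets",
    "to_anndata",
    "from_anndata",
]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix in (".h5", ".hdf5"):
        return "h5"
    raise ValueError(f"cannot infer matrix format from {path.name!r}")


def _label_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_barcodes.tsv"), Path(f"{stem}_genes.tsv")


def _read_labels(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"{what} label file not found: {path}")
    labels = [line.rstrip("\n") for line in path.read_text().splitlines() if line.strip()]
    if not labels:
        raise ValueError(f"{what} label file {path} is empty")
    return labels


def read_matrix(path, format: str | None = None, raw_counts: bool = False) -> ExpressionMatrix:
    """Read an expression matrix; format inferred from the extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "mtx":
        try:
            values = scipy.io.mmread(str(path))
        except Exception as exc:  # noqa: BLE001 - surface parse position
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        values = sp.csr_matrix(values)
        cells_p, genes_p = _label_paths(path)
        cells = _read_labels(cells_p, "cell")
        genes = _read_labels(genes_p, "gene")
        if values.shape != (len(cells), len(genes)):
            if values.shape == (len(genes), len(cells)):
                logger.info(
                    "read_matrix: %s stored genes x cells; transposing", path.name
                )
                values = sp.csr_matrix(values.T)
            else:
                raise ValueError(
                    f"label files do not match matrix shape {values.shape}: "
                    f"{len(cells)} cells, {len(genes)} genes"
                )
        return ExpressionMatrix(values, cells, genes, raw_counts)

    if fmt in ("csv", "tsv"):
        import pandas as pd

        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if df.empty:
            raise ValueError(f"empty matrix file: {path}")
        return ExpressionMatrix(
            df.to_numpy(dtype=float), [str(i) for i in df.index],
            [str(c) for c in df.columns], raw_counts,
        )

    if fmt == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            if "X" not in f:
                raise ValueError(f"{path}: missing dataset /X")
            X = f["X"]
            if isinstance(X, h5py.Group):
                values = sp.csr_matrix(
                    (X["data"][:], X["indices"][:], X["indptr"][:]),
                    shape=tuple(X["shape"][:]),
                )
            else:
                values = X[:]
            cells = [x.decode() if isinstance(x, bytes) else str(x) for x in f["obs_names"][:]]
            genes = [x.decode() if isinstance(x, bytes) else str(x) for x in f["var_names"][:]]
        return ExpressionMatrix(values, cells, genes, raw_counts)

    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(X: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write losslessly in the requested (or inferred) format."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if fmt == "mtx":
        values = X.values if sp.issparse(X.values) else sp.csr_matrix(X.values)
        scipy.io.mmwrite(str(path), values, precision=17)
        cells_p, genes_p = _label_paths(path)
        cells_p.write_text("\n".join(X.cell_ids) + "\n")
        genes_p.write_text("\n".join(X.gene_ids) + "\n")
        return

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        X.to_dataframe().to_csv(path, sep=sep, float_format="%.17g")
        return

    if fmt == "h5":
        import h5py

        with h5py.File(path, "w") as f:
            if sp.issparse(X.values):
                csr = X.values.tocsr()
                g = f.create_group("X")
                g.create_dataset("data", data=csr.data)
                g.create_dataset("indices", data=csr.indices)
                g.create_dataset("indptr", data=csr.indptr)
                g.create_dataset("shape", data=np.asarray(csr.shape))
            else:
                f.create_dataset("X", data=np.asarray(X.values))
            str_dt = h5py.string_dtype()
            f.create_dataset("obs_names", data=np.asarray(X.cell_ids, dtype=object), dtype=str_dt)
            f.create_dataset("var_names", data=np.asarray(X.gene_ids, dtype=object), dtype=str_dt)
        return

    raise ValueError(f"unknown format {fmt!r}")


def write_graph_triplets(W, path) -> None:
    """Write a sparse matrix as 0-based ``i j value`` triplet text."""
    path = Path(path)
    coo = sp.coo_matrix(W)
    lines = [f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}"]
    lines += [f"{i} {j} {v:.17g}" for i, j, v in zip(coo.row, coo.col, coo.data)]
    path.write_text("\n".join(lines) + "\n")


def read_graph_triplets(path) -> sp.csr_matrix:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty graph file: {path}")
    try:
        n, m, nnz = (int(x) for x in lines[0].split())
        rows, cols, vals = [], [], []
        for ln, line in enumerate(lines[1 : nnz + 1], start=2):
            i, j, v = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed triplet file {path} near line {ln}: {exc}") from exc
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, m))


def to_anndata(X: ExpressionMatrix):
    """Convert to an AnnData object (anndata required)."""
    import anndata as ad
    import pandas as pd

    return ad.AnnData(
        X=X.values.copy(),
        obs=pd.DataFrame(index=X.cell_ids),
        var=pd.DataFrame(index=X.gene_ids),
    )


def from_anndata(adata, raw_counts: bool = False) -> ExpressionMatrix:
    return ExpressionMatrix(
        adata.X.copy(), list(adata.obs_names), list(adata.var_names), raw_counts
    )
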