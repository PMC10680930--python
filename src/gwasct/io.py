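"""Count-matrix and annotation ingestion.

One contract for all sources: a gene x cell matrix with gene labels plus a
cell-annotation table carrying one column per annotation level.  Supported
matrix formats: Matrix Market (.mtx, with sidecar gene/cell label files),
dense TSV (genes as rows) and AnnData .h5ad (cells x genes on disk, as is
conventional there; transposed on read).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd


def read_counts(path: str, genes_path: str | None = None,
                cells_path: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a count matrix; returns (gene x cell array, gene ids, cell ids)."""
    if path.endswith(".mtx"):
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense())
        base = path[: -len(".mtx")]
        genes_path = genes_path or base + ".genes.txt"
        cells_path = cells_path or base + ".cells.txt"
        genes = [line.strip() for line in open(genes_path)]
        cells = [line.strip() for line in open(cells_path)]
        return mat, genes, cells
    if path.endswith(".h5ad"):
        import anndata

        ad = anndata.read_h5ad(path)
        X = ad.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        return X.T, list(ad.var_names), list(ad.obs_names)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index), list(df.columns)


def write_counts_mtx(counts: np.ndarray, genes: list[str], cells: list[str],
                     path: str) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(path, coo_matrix(counts))
    base = path[: -len(".mtx")] if path.endswith(".mtx") else path
    with open(base + ".genes.txt", "w") as fh:
        fh.write("\n".join(genes) + "\n")
    with open(base + ".cells.txt", "w") as fh:
        fh.write("\n".join(cells) + "\n")


def read_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValueError("annotation table needs a cell_id column")
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
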