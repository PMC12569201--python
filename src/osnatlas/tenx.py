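"""Reading and writing 10x-style MTX triplet directories.

On disk the matrix follows the 10x Chromium convention: ``matrix.mtx``
holds genes x cells integer counts in MatrixMarket coordinate format,
``features.tsv`` one gene per line, ``barcodes.tsv`` one cell barcode per
line.  In memory we use AnnData with cells as observations, so the matrix
is transposed on the way in and out.  The round trip is bit-exact on
counts and order-preserving on genes and barcodes.
"""

from __future__ import annotations

import io
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Malformed MTX triplet directory."""


def write_tenx(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write ``adata`` (cells x genes, nonnegative integer counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    dense_check = X.data if X.nnz else np.array([0])
    if (dense_check < 0).any() or not np.allclose(dense_check, np.round(dense_check)):
        raise FormatError("counts must be nonnegative integers")
    mat = sparse.coo_matrix(X.T.astype(np.int64))  # genes x cells on disk
    spio.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return outdir


def read_tenx(indir: str | Path) -> ad.AnnData:
    """Read an MTX triplet directory back into AnnData (cells x genes)."""
    indir = Path(indir)
    mtx = indir / "matrix.mtx"
    for f in (mtx, indir / "features.tsv", indir / "barcodes.tsv"):
        if not f.exists():
            raise FormatError(f"missing file: {f}")
    try:
        mat = spio.mmread(str(mtx))
    except Exception as exc:  # malformed header or entries
        raise FormatError(f"{mtx}: {exc}") from exc
    if not np.issubdtype(np.asarray(mat.data if sparse.issparse(mat) else mat).dtype, np.integer):
        data = mat.data if sparse.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{mtx}: non-integer entries")
    genes = _read_lines(indir / "features.tsv")
    barcodes = _read_lines(indir / "barcodes.tsv")
    mat = sparse.csr_matrix(mat.T.astype(np.int64))  # back to cells x genes
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"{mtx}: dimensions {mat.T.shape} do not match "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    return ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def _read_lines(path: Path) -> list[str]:
    with io.open(path, "r", encoding="utf-8") as fh:
        return [ln.split("\t")[0].strip() for ln in fh if ln.strip()]
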