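"""Readers and writers for the on-disk formats: MTX / dense TSV counts,
annotation TSV, ground-truth TSV, and float-stable tabular output."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .errors import ConfigError, SchemaError

FLOAT_FORMAT = "%.6g"  # 6 significant digits: diff-able, bit-stable output


def read_counts_mtx(mtx_path, genes_path, barcodes_path, orientation: str = "cells-by-genes") -> AnnData:
    """Read a MatrixMarket triplet with row/column name files into AnnData.

    ``orientation`` declares what the MTX rows are: ``"cells-by-genes"`` or
    ``"genes-by-cells"`` (the 10x convention).
    """
    mat = spio.mmread(str(mtx_path)).tocsr()
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    cells = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    if orientation == "genes-by-cells":
        mat = mat.T.tocsr()
    elif orientation != "cells-by-genes":
        raise ConfigError(f"unknown orientation: {orientation!r}")
    if mat.shape != (len(cells), len(genes)):
        raise SchemaError(
            f"matrix shape {mat.shape} does not match {len(cells)} cells x {len(genes)} genes"
        )
    if (mat.data < 0).any():
        raise SchemaError("count matrix contains negative entries")
    return AnnData(
        X=mat, obs=pd.DataFrame(index=cells), var=pd.DataFrame(index=genes)
    )


def read_counts_tsv(path, orientation: str = "cells-by-genes") -> AnnData:
    """Read a dense TSV (first column = row names, header = column names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes-by-cells":
        df = df.T
    elif orientation != "cells-by-genes":
        raise ConfigError(f"unknown orientation: {orientation!r}")
    if (df.to_numpy() < 0).any():
        raise SchemaError("count matrix contains negative entries")
    return AnnData(
        X=df.to_numpy(),
        obs=pd.DataFrame(index=df.index.astype(str)),
        var=pd.DataFrame(index=df.columns.astype(str)),
    )


def read_annotation(path) -> pd.DataFrame:
    """Annotation TSV with columns cell, cluster, donor (total_counts optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "cluster": str, "donor": str})
    missing = {"cell", "cluster", "donor"} - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table missing column(s): {sorted(missing)}")
    if df["cluster"].isna().any() or (df["cluster"].astype(str).str.len() == 0).any():
        raise SchemaError("annotation contains empty cluster labels")
    return df


def attach_annotation(adata: AnnData, annot: pd.DataFrame) -> AnnData:
    """Align an annotation table to the matrix cells (each annotated exactly once)."""
    if annot["cell"].duplicated().any():
        dupes = annot.loc[annot["cell"].duplicated(), "cell"].tolist()
        raise SchemaError(f"cells annotated more than once: {dupes[:5]}")
    annot = annot.set_index("cell")
    missing = [c for c in adata.obs_names if c not in annot.index]
    if missing:
        raise SchemaError(f"cells missing from annotation: {missing[:5]}")
    adata.obs["cluster"] = annot.loc[adata.obs_names, "cluster"].astype(str).to_numpy()
    adata.obs["donor"] = annot.loc[adata.obs_names, "donor"].astype(str).to_numpy()
    if "total_counts" in annot.columns:
        adata.obs["total_counts"] = annot.loc[adata.obs_names, "total_counts"].to_numpy()
    else:
        X = adata.X
        adata.obs["total_counts"] = (
            np.asarray(X.sum(axis=1)).ravel() if sparse.issparse(X) else np.asarray(X).sum(axis=1)
        )
    return adata


def write_dataset(adata: AnnData, outdir) -> dict[str, Path]:
    """Write counts as MTX + names + annotation TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / "counts.mtx",
        "genes": outdir / "genes.txt",
        "barcodes": outdir / "barcodes.txt",
        "annotation": outdir / "annotation.tsv",
    }
    X = adata.X
    mat = sparse.coo_matrix(X) if not sparse.issparse(X) else X.tocoo()
    spio.mmwrite(str(paths["mtx"]), mat, field="integer")
    paths["genes"].write_text("\n".join(adata.var_names) + "\n")
    paths["barcodes"].write_text("\n".join(adata.obs_names) + "\n")
    annot = pd.DataFrame(
        {
            "cell": adata.obs_names,
            "cluster": adata.obs["cluster"].astype(str),
            "donor": adata.obs["donor"].astype(str),
            "total_counts": adata.obs["total_counts"].astype(int),
        }
    )
    annot.to_csv(paths["annotation"], sep="\t", index=False)
    return paths


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """TSV with headers, floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
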