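"""Standard-format IO: MatrixMarket count directories, TSV tables, truth JSON.

Counts are stored 10x-style: ``matrix.mtx`` (genes x cells, 1-based
coordinate MatrixMarket, integer field) with order-aligned ``genes.tsv``
and ``barcodes.tsv`` sidecars. Round-trips are lossless for integer
counts. ``scipy.io.mmread`` performs the parsing and rejects malformed
(e.g. 0-based) indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .datatypes import Embedding, LabelSet, TruthRecord

__all__ = [
    "write_mtx",
    "read_mtx",
    "write_embedding_tsv",
    "read_embedding_tsv",
    "write_labels_tsv",
    "read_labels_tsv",
    "write_tsv_table",
    "read_tsv_table",
    "write_truth_json",
    "read_truth_json",
]


def write_mtx(adata: AnnData, outdir: str | Path) -> Path:
    """Write counts as matrix.mtx + genes.tsv + barcodes.tsv (+ obs/var TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X.tocoo() if sp.issparse(adata.X) else sp.coo_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(int), field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "obs.tsv", sep="\t", index_label="cell_id")
    if len(adata.var.columns):
        adata.var.to_csv(outdir / "var.tsv", sep="\t", index_label="gene")
    return outdir


def read_mtx(indir: str | Path) -> AnnData:
    """Read a matrix.mtx + sidecars directory back into AnnData (cells x genes)."""
    indir = Path(indir)
    M = scipy.io.mmread(str(indir / "matrix.mtx")).tocsr()  # genes x cells
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if M.shape[0] != len(genes) or M.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix is {M.shape[0]} genes x {M.shape[1]} cells but sidecars list "
            f"{len(genes)} genes / {len(barcodes)} barcodes"
        )
    obs = pd.DataFrame(index=barcodes.to_numpy())
    var = pd.DataFrame(index=genes.to_numpy())
    if (indir / "obs.tsv").exists():
        obs = pd.read_csv(indir / "obs.tsv", sep="\t", index_col="cell_id")
        obs.index = obs.index.astype(str)
    if (indir / "var.tsv").exists():
        var = pd.read_csv(indir / "var.tsv", sep="\t", index_col="gene")
        var.index = var.index.astype(str)
    return AnnData(X=M.T.tocsr(), obs=obs, var=var)


def write_embedding_tsv(embedding: Embedding, path: str | Path) -> Path:
    path = Path(path)
    embedding.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_embedding_tsv(path: str | Path, provenance: str = "") -> Embedding:
    df = pd.read_csv(path, sep="\t")
    dims = [c for c in df.columns if c.startswith("dim_")]
    return Embedding(
        cell_ids=df["cell_id"].astype(str).to_numpy(dtype=object),
        coords=df[dims].to_numpy(dtype=float),
        provenance=provenance or str(path),
    )


def write_labels_tsv(labels: LabelSet, path: str | Path) -> Path:
    path = Path(path)
    labels.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_labels_tsv(path: str | Path) -> LabelSet:
    df = pd.read_csv(path, sep="\t")
    return LabelSet(
        cell_ids=df["cell_id"].astype(str).to_numpy(dtype=object),
        labels=df["label"].to_numpy(dtype=object),
        confidence=df["confidence"].to_numpy(dtype=float) if "confidence" in df else None,
        refined_from=df["refined_from"].to_numpy(dtype=object) if "refined_from" in df else None,
    )


def write_tsv_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_truth_json(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
    return path


def read_truth_json(path: str | Path) -> TruthRecord:
    return TruthRecord.from_json_dict(json.loads(Path(path).read_text()))
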