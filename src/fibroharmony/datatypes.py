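"""Shared domain types for the fibroblast-state harmonization pipeline.

Expression data travels as :class:`anndata.AnnData` with the following
conventions, used consistently by every module:

* ``adata.X`` — raw UMI counts, sparse CSR, cells x genes.
* ``adata.layers["lognorm"]`` — library-size normalized (counts per 10k)
  log1p expression; created on demand by :func:`log_normalize`.
* ``adata.obs`` — per-cell metadata: ``batch``, ``population`` and, for
  mixed captures, ``capture_type``; spatial spot tables additionally carry
  ``x``, ``y`` and ``majority_celltype``.
* ``adata.var`` — gene metadata; boolean panels ``is_ribosomal`` and
  ``is_lncRNA`` flag the gene sets used for cell/nucleus discrimination.

The light dataclasses below (``Embedding``, ``LabelSet``, ``PurityMatrix``,
...) carry the non-expression objects the pipeline passes between stages and
validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "Embedding",
    "LabelSet",
    "PurityMatrix",
    "OverlapResult",
    "WeightedSignature",
    "CVReport",
    "TruthRecord",
    "log_normalize",
    "MARKER_TABLE_COLUMNS",
    "validate_marker_table",
    "validate_regulon_table",
]

MARKER_TABLE_COLUMNS = (
    "population",
    "gene",
    "log2_fold_change",
    "p_raw",
    "p_adj",
    "frac_expr_in",
    "frac_expr_out",
)


def log_normalize(adata: AnnData, target_sum: float = 1e4, layer: str = "lognorm") -> AnnData:
    """Add a counts-per-``target_sum`` log1p layer computed from ``adata.X``.

    Idempotent: an existing layer of the same name is left untouched.
    Cells with zero total counts are left all-zero rather than NaN.
    """
    if layer in adata.layers:
        return adata
    X = adata.X
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        scale = np.divide(target_sum, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
        norm = sp.diags(scale) @ X.tocsr()
        norm = norm.astype(float)
        norm.data = np.log1p(norm.data)
    else:
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
        norm = np.log1p(X * scale[:, None])
    adata.layers[layer] = norm
    return adata


@dataclass
class Embedding:
    """Cell coordinates in an integrated low-dimensional space.

    Parameters
    ----------
    cell_ids
        Unique cell identifiers, one per row of ``coords``.
    coords
        ``(n_cells, d)`` real matrix, ``d >= 2``, all finite.
    provenance
        Free-text tag recording where the embedding came from
        (e.g. ``"ideal-factor-scores"`` or ``"pca-lognorm"``).
    """

    cell_ids: np.ndarray
    coords: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding coords must be 2-D with d >= 2")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids and coords row count differ")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids in embedding")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in embedding")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim_{i + 1}" for i in range(self.n_dims)]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "cell_id", self.cell_ids)
        return df


@dataclass
class LabelSet:
    """Per-cell categorical state labels with a closed vocabulary.

    ``labels`` may contain ``None`` for unlabeled cells; operations that
    require complete labels refuse them unless told otherwise.
    ``refined_from`` and ``confidence`` are populated by refinement or
    classifier prediction and are otherwise ``None``.
    """

    cell_ids: np.ndarray
    labels: np.ndarray
    vocabulary: tuple = ()
    refined_from: np.ndarray | None = None
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("cell_ids and labels length differ")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids in label set")
        observed = {l for l in self.labels if l is not None and not (isinstance(l, float) and np.isnan(l))}
        if not self.vocabulary:
            self.vocabulary = tuple(sorted(observed, key=str))
        else:
            self.vocabulary = tuple(self.vocabulary)
            extra = observed - set(self.vocabulary)
            if extra:
                raise ValueError(f"labels outside declared vocabulary: {sorted(map(str, extra))}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if np.nanmin(self.confidence, initial=0.0) < 0 or np.nanmax(self.confidence, initial=0.0) > 1:
                raise ValueError("confidence values must lie in [0, 1]")
        if self.refined_from is not None:
            self.refined_from = np.asarray(self.refined_from, dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def missing_mask(self) -> np.ndarray:
        return np.array(
            [l is None or (isinstance(l, float) and np.isnan(l)) for l in self.labels], dtype=bool
        )

    def aligned_to(self, embedding: Embedding) -> None:
        """Raise unless cell ids match the embedding 1:1 in order."""
        if self.n_cells != embedding.n_cells or not np.array_equal(self.cell_ids, embedding.cell_ids):
            raise ValueError("label set and embedding cell_ids do not align 1:1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "label": self.labels})
        if self.confidence is not None:
            df["confidence"] = self.confidence
        if self.refined_from is not None:
            df["refined_from"] = self.refined_from
        return df


@dataclass
class PurityMatrix:
    """Average neighbor-label composition per label class, in percent.

    ``values.loc[A, B]`` is the mean percentage of the ``k_used`` nearest
    neighbors of class-A cells that carry label B; every row sums to 100.
    """

    values: pd.DataFrame
    k_used: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size:
            if np.any(v < -1e-9) or np.any(v > 100 + 1e-9):
                raise ValueError("purity values must lie in [0, 100]")
            rowsums = v.sum(axis=1)
            if not np.allclose(rowsums, 100.0, atol=1e-6):
                raise ValueError("purity matrix rows must sum to 100")

    @property
    def labels(self) -> list:
        return list(self.values.index)


@dataclass(frozen=True)
class OverlapResult:
    """Jaccard coefficient and one-sided Fisher enrichment for two gene sets."""

    jaccard: float
    n_intersect: int
    n_a: int
    n_b: int
    n_universe: int
    fisher_p: float

    def __post_init__(self) -> None:
        union = self.n_a + self.n_b - self.n_intersect
        expect = 0.0 if union == 0 else self.n_intersect / union
        if abs(self.jaccard - expect) > 1e-12:
            raise ValueError("jaccard inconsistent with counts")
        if not (0 <= self.fisher_p <= 1):
            raise ValueError("fisher_p outside [0, 1]")


@dataclass
class WeightedSignature:
    """Named positively-weighted gene signature (e.g. MYO or MFC score)."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        self.weights = dict(self.weights)
        if len(self.weights) < 1:
            raise ValueError("signature must contain at least one gene")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("signature weights must be positive")


@dataclass
class CVReport:
    """Pooled out-of-fold cross-validation metrics.

    ``per_class`` has one row per class with columns ``sensitivity``,
    ``specificity`` and ``balanced_accuracy``; ``confusion`` rows are truth,
    columns predictions, entries pooled counts.
    """

    per_class: pd.DataFrame
    confusion: pd.DataFrame
    macro_balanced_accuracy: float
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        ba = (self.per_class["sensitivity"] + self.per_class["specificity"]) / 2.0
        if not np.allclose(ba, self.per_class["balanced_accuracy"]):
            raise ValueError("balanced accuracy identity violated")


@dataclass
class TruthRecord:
    """Simulator ground truth for downstream recovery tests.

    Attributes
    ----------
    cell_labels
        ``cell_id -> population`` for every simulated cell.
    marker_truth
        ``population -> {gene: planted log2 fold change}``.
    batch_params
        genes x batches DataFrame of per-gene log-scale batch factors.
    spot_composition
        ``spot_id -> (cell_ids, weights)``; weights sum to 1 per spot.
    capture_type
        ``cell_id -> "cell" | "nucleus"`` for mixture datasets.
    """

    cell_labels: pd.Series
    marker_truth: dict = field(default_factory=dict)
    batch_params: pd.DataFrame | None = None
    spot_composition: dict = field(default_factory=dict)
    capture_type: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.cell_labels.index.duplicated().any():
            raise ValueError("duplicate cell ids in truth cell_labels")
        for spot, (cells, weights) in self.spot_composition.items():
            w = np.asarray(weights, dtype=float)
            if len(cells) != len(w):
                raise ValueError(f"spot {spot}: cells and weights length differ")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"spot {spot}: composition weights must sum to 1")

    def to_json_dict(self) -> dict:
        out = {
            "cell_labels": {str(k): str(v) for k, v in self.cell_labels.items()},
            "marker_truth": {
                str(p): {str(g): float(f) for g, f in genes.items()}
                for p, genes in self.marker_truth.items()
            },
            "spot_composition": {
                str(s): {"cells": [str(c) for c in cells], "weights": [float(w) for w in weights]}
                for s, (cells, weights) in self.spot_composition.items()
            },
        }
        if self.batch_params is not None:
            out["batch_params"] = {
                str(b): self.batch_params[b].astype(float).to_dict() for b in self.batch_params.columns
            }
        if self.capture_type is not None:
            out["capture_type"] = {str(k): str(v) for k, v in self.capture_type.items()}
        return out

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "TruthRecord":
        batch_params = None
        if "batch_params" in d:
            batch_params = pd.DataFrame({b: pd.Series(v) for b, v in d["batch_params"].items()})
        capture = pd.Series(d["capture_type"]) if "capture_type" in d else None
        spots = {
            s: (list(v["cells"]), list(map(float, v["weights"])))
            for s, v in d.get("spot_composition", {}).items()
        }
        return cls(
            cell_labels=pd.Series(d["cell_labels"]),
            marker_truth={p: dict(g) for p, g in d.get("marker_truth", {}).items()},
            batch_params=batch_params,
            spot_composition=spots,
            capture_type=capture,
        )


def validate_marker_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check marker-table column contract and probability invariants."""
    missing = [c for c in MARKER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    if len(df):
        if df.duplicated(subset=["population", "gene"]).any():
            raise ValueError("duplicate (population, gene) pair in marker table")
        for col in ("p_raw", "p_adj"):
            v = df[col].to_numpy(dtype=float)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{col} outside [0, 1]")
        if np.any(df["p_adj"].to_numpy(float) < df["p_raw"].to_numpy(float) - 1e-12):
            raise ValueError("p_adj must be >= p_raw")
    return df


def validate_regulon_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (tf, target, weight) regulon table contract."""
    for col in ("tf", "target", "weight"):
        if col not in df.columns:
            raise ValueError(f"regulon table missing column: {col}")
    if df.duplicated(subset=["tf", "target"]).any():
        raise ValueError("duplicate target within a regulon")
    return df


def labels_from_obs(adata: AnnData, column: str, vocabulary: Sequence[str] | None = None) -> LabelSet:
    """Build a LabelSet from an ``adata.obs`` column."""
    return LabelSet(
        cell_ids=np.asarray(adata.obs_names, dtype=object),
        labels=adata.obs[column].to_numpy(dtype=object),
        vocabulary=tuple(vocabulary) if vocabulary else (),
    )
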