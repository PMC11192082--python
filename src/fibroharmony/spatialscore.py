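"""Marker-weighted state scores on spatial transcriptomics spots.

Spots live in an AnnData (obs: ``x``, ``y``, ``majority_celltype``).
A :class:`~.datatypes.WeightedSignature` (e.g. MYO or MFC, built from
reference marker fold changes) is scored per spot as a weighted sum of
normalized expression; spots can be filtered to the majority-fibroblast
subset before mapping, and two scores are combined into a bivariate
quantile-class map.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .datatypes import WeightedSignature, log_normalize

logger = logging.getLogger(__name__)

__all__ = ["spot_score", "signature_from_markers", "filter_majority", "bivariate_map"]


def signature_from_markers(
    markers: pd.DataFrame, name: str, top_n: int = 50, weight_col: str = "log2_fold_change"
) -> WeightedSignature:
    """Signature from a marker table: top-``top_n`` markers by adjusted p,
    weighted by fold change (weights must come out positive)."""
    top = markers.nsmallest(top_n, "p_adj")
    return WeightedSignature(name=name, weights=dict(zip(top["gene"], top[weight_col])))


def spot_score(spots: AnnData, sig: WeightedSignature, normalize: bool = True) -> pd.Series:
    """Weighted-sum signature score per spot.

    ``score_s = sum_g w_g * expr(s, g)`` over the signature genes present
    in the matrix, where ``expr`` is counts-per-10k log1p when
    ``normalize`` (default) and raw counts otherwise. Signature genes
    absent from the matrix are ignored; if none is present, error.
    """
    present = [g for g in sig.weights if g in spots.var_names]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the spot matrix")
    if normalize:
        log_normalize(spots)
        X = spots.layers["lognorm"]
    else:
        X = spots.X
    col = pd.Index(spots.var_names).get_indexer(present)
    sub = X[:, col]
    sub = sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)
    w = np.array([sig.weights[g] for g in present])
    return pd.Series(sub @ w, index=spots.obs_names, name=sig.name)


def filter_majority(spots: AnnData, celltype: str = "Fibroblast") -> AnnData:
    """Retain spots whose majority annotation equals ``celltype``."""
    if "majority_celltype" not in spots.obs:
        raise ValueError("spot table lacks a majority_celltype annotation column")
    mask = (spots.obs["majority_celltype"] == celltype).to_numpy()
    if not mask.any():
        logger.warning("no spot has majority celltype %r; returning empty table", celltype)
    return spots[mask].copy()


def _quantile_classes(scores: np.ndarray, n_levels: int) -> np.ndarray:
    if np.allclose(scores, scores[0]):
        logger.warning("constant score vector; all spots assigned class 0")
        return np.zeros(len(scores), dtype=int)
    order = np.argsort(scores, kind="stable")
    classes = np.empty(len(scores), dtype=int)
    classes[order] = np.floor(np.arange(len(scores)) * n_levels / len(scores)).astype(int)
    return classes


def bivariate_map(
    scores_a: pd.Series,
    scores_b: pd.Series,
    coords: pd.DataFrame,
    n_levels: int = 3,
    out_image: str | None = None,
) -> pd.DataFrame:
    """Bivariate quantile-class assignment of two spot scores.

    Each score is cut into ``n_levels`` rank-quantile classes (equal
    occupancy up to +-1 for distinct scores); a spot lands in the
    ``(class_a, class_b)`` cell of an n x n bivariate palette. Returns the
    class assignments as data; optionally renders the spatial map.
    """
    if not (len(scores_a) == len(scores_b) == len(coords)):
        raise ValueError("score vectors and coordinates are not aligned")
    ca = _quantile_classes(scores_a.to_numpy(dtype=float), n_levels)
    cb = _quantile_classes(scores_b.to_numpy(dtype=float), n_levels)
    out = pd.DataFrame(
        {
            "x": coords["x"].to_numpy(),
            "y": coords["y"].to_numpy(),
            f"class_{scores_a.name or 'a'}": ca,
            f"class_{scores_b.name or 'b'}": cb,
        },
        index=scores_a.index,
    )
    out["palette_cell"] = [f"{a}-{b}" for a, b in zip(ca, cb)]
    if out_image is not None:
        _render_bivariate(out, ca, cb, n_levels, out_image, scores_a.name, scores_b.name)
    return out


def _render_bivariate(df, ca, cb, n_levels, path, name_a, name_b):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # corner-anchored bivariate palette: a drives magenta, b drives cyan
    r = 0.15 + 0.85 * ca / max(n_levels - 1, 1)
    b = 0.15 + 0.85 * cb / max(n_levels - 1, 1)
    colors = np.stack([r, 0.15 + 0.0 * r, b], axis=1)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df["x"], df["y"], c=colors, s=12)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"bivariate {name_a or 'A'} x {name_b or 'B'}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
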