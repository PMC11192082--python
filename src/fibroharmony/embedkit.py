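"""Label harmonization and integration-quality metrics on a shared embedding.

Two operations from the harmonization workflow live here:

* :func:`refine_labels` — refine cluster identities by majority vote over
  each cell's 25 nearest neighbors in the integrated space, the step used
  to harmonize cluster IDs across datasets after integration.
* :func:`neighbor_purity` — for each cluster, the average percentage of
  each cell's top-200 nearest neighbors belonging to every cluster; the
  heatmap diagnostic used to compare integration methods (batch mixing
  vs. retention of biological states).

Neighbor search is exact. Below ``_EXACT_FULL_N`` cells the full pairwise
distance matrix is formed and ties are resolved by (distance, cell_id)
lexicographic order, making results fully deterministic and identical to a
brute-force oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import Embedding, LabelSet, PurityMatrix

logger = logging.getLogger(__name__)

__all__ = ["NeighborIndex", "knn_index", "refine_labels", "neighbor_purity", "batch_mixing_report"]

_EXACT_FULL_N = 4096  # full-matrix lexicographic path below this size


@dataclass
class NeighborIndex:
    """k nearest other cells per cell, deterministically ordered."""

    cell_ids: np.ndarray
    indices: np.ndarray   # (n, k) integer positions into cell_ids
    distances: np.ndarray  # (n, k)
    k: int
    metric: str = "euclidean"


def knn_index(embedding: Embedding, k: int, metric: str = "euclidean") -> NeighborIndex:
    """Exact k-nearest-neighbor lists with the cell itself excluded.

    Neighbors are ordered by (distance, cell_id); distance ties are thus
    broken toward the lexicographically smaller cell identifier.
    """
    n = embedding.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = embedding.coords
    id_rank = np.argsort(np.argsort(embedding.cell_ids, kind="stable"), kind="stable")

    if n <= _EXACT_FULL_N:
        D = cdist(coords, coords, metric=metric)
        np.fill_diagonal(D, np.inf)
        # lexsort: primary key distance, secondary key cell-id rank
        order = np.lexsort((np.broadcast_to(id_rank, (n, n)), D), axis=1)
        idx = order[:, :k]
        dist = np.take_along_axis(D, idx, axis=1)
        return NeighborIndex(embedding.cell_ids, idx, dist, k, metric)

    from sklearn.neighbors import NearestNeighbors

    pad = min(n - 1, k + 8)
    nn = NearestNeighbors(n_neighbors=pad + 1, metric=metric).fit(coords)
    dist, idx = nn.kneighbors(coords)
    out_idx = np.empty((n, k), dtype=int)
    out_dist = np.empty((n, k))
    for i in range(n):
        mask = idx[i] != i
        cand_i, cand_d = idx[i][mask], dist[i][mask]
        order = np.lexsort((id_rank[cand_i], cand_d))
        out_idx[i] = cand_i[order][:k]
        out_dist[i] = cand_d[order][:k]
    return NeighborIndex(embedding.cell_ids, out_idx, out_dist, k, metric)


def refine_labels(
    embedding: Embedding,
    labels: LabelSet,
    k: int = 25,
    allow_missing: bool = False,
    index: NeighborIndex | None = None,
) -> LabelSet:
    """Refine labels by majority vote over each cell's k nearest neighbors.

    Each cell receives the modal label among its ``k`` nearest other cells;
    ``confidence`` is the modal vote fraction and ``refined_from``
    preserves the input label. Ties go to the cell's original label when it
    is among the tied modes, else to the lexicographically smallest tied
    label (refinement stays conservative).

    Unlabeled cells raise unless ``allow_missing``; then they neither vote
    nor get refined.
    """
    labels.aligned_to(embedding)
    missing = labels.missing_mask()
    if missing.any() and not allow_missing:
        raise ValueError(
            f"{int(missing.sum())} unlabeled cells present; pass allow_missing=True to skip them"
        )
    idx = index if index is not None else knn_index(embedding, k)
    if idx.k < k:
        raise ValueError("precomputed index has fewer neighbors than requested k")
    vocab = list(labels.vocabulary)
    code = {lab: c for c, lab in enumerate(vocab)}
    labarr = labels.labels

    refined = labarr.copy()
    confidence = np.full(labels.n_cells, np.nan)
    for i in range(labels.n_cells):
        if missing[i]:
            continue
        votes = np.zeros(len(vocab))
        n_votes = 0
        for j in idx.indices[i, :k]:
            if not missing[j]:
                votes[code[labarr[j]]] += 1
                n_votes += 1
        if n_votes == 0:
            confidence[i] = np.nan
            continue
        top = votes.max()
        tied = [vocab[c] for c in np.flatnonzero(votes == top)]
        if labarr[i] in tied:
            refined[i] = labarr[i]
        else:
            refined[i] = sorted(tied, key=str)[0]
        confidence[i] = top / n_votes
    return LabelSet(
        cell_ids=labels.cell_ids,
        labels=refined,
        vocabulary=labels.vocabulary,
        refined_from=labarr.copy(),
        confidence=confidence,
    )


def neighbor_purity(
    embedding: Embedding,
    labels: LabelSet,
    k: int = 200,
    index: NeighborIndex | None = None,
) -> PurityMatrix:
    """Average neighbor-label composition per label class, in percent.

    Entry (A, B) is the mean over class-A cells of the percentage of their
    ``k`` nearest neighbors carrying label B. Rows sum to 100. Vocabulary
    classes with zero cells are dropped from the rows with a warning (they
    remain as columns, necessarily all-zero).
    """
    labels.aligned_to(embedding)
    if labels.missing_mask().any():
        raise ValueError("neighbor_purity requires fully labeled cells")
    idx = index if index is not None else knn_index(embedding, k)
    if idx.k < k:
        raise ValueError("precomputed index has fewer neighbors than requested k")
    vocab = list(labels.vocabulary)
    code = {lab: c for c, lab in enumerate(vocab)}
    codes = np.array([code[l] for l in labels.labels])

    neigh_codes = codes[idx.indices[:, :k]]                      # (n, k)
    onehot = np.zeros((labels.n_cells, len(vocab)))
    for c in range(len(vocab)):
        onehot[:, c] = (neigh_codes == c).sum(axis=1)
    pct = onehot * (100.0 / k)

    rows = []
    kept = []
    for c, lab in enumerate(vocab):
        mask = codes == c
        if not mask.any():
            logger.warning("label class %r has 0 cells; dropped from purity rows", lab)
            continue
        kept.append(lab)
        rows.append(pct[mask].mean(axis=0))
    values = pd.DataFrame(np.vstack(rows), index=kept, columns=vocab)
    return PurityMatrix(values=values, k_used=k)


def batch_mixing_report(
    embedding: Embedding,
    batch_labels: LabelSet,
    state_labels: LabelSet,
    k: int = 200,
) -> dict:
    """Joint batch-mixing / state-retention diagnostic on one embedding.

    Returns the two purity matrices plus two scalars: the batch-mixing
    score (mean off-diagonal batch purity; higher = better mixed) and the
    state-retention score (mean diagonal state purity; higher = states
    preserved).
    """
    batch_labels.aligned_to(embedding)
    state_labels.aligned_to(embedding)
    idx = knn_index(embedding, k)
    by_batch = neighbor_purity(embedding, batch_labels, k, index=idx)
    by_state = neighbor_purity(embedding, state_labels, k, index=idx)

    def _mean_offdiag(pm: PurityMatrix) -> float:
        v = pm.values
        vals = [v.loc[r, c] for r in v.index for c in v.columns if r != c]
        return float(np.mean(vals)) if vals else 0.0

    def _mean_diag(pm: PurityMatrix) -> float:
        return float(np.mean([pm.values.loc[r, r] for r in pm.values.index if r in pm.values.columns]))

    return {
        "purity_by_batch": by_batch,
        "purity_by_state": by_state,
        "batch_mixing_score": _mean_offdiag(by_batch),
        "state_retention_score": _mean_diag(by_state),
        "k": k,
    }
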