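"""kNN refinement and neighbor purity against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from fibroharmony.datatypes import Embedding, LabelSet
from fibroharmony.embedkit import (
    batch_mixing_report,
    knn_index,
    neighbor_purity,
    refine_labels,
)


def _embedding(coords, ids=None, tag="test"):
    coords = np.asarray(coords, dtype=float)
    if ids is None:
        ids = [f"c{i:03d}" for i in range(len(coords))]
    return Embedding(cell_ids=np.asarray(ids, dtype=object), coords=coords, provenance=tag)


def brute_knn(coords, ids, k):
    """Exhaustive (distance, id) ordered neighbor lists; the oracle."""
    n = len(coords)
    out = []
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        cand = [(d[j], str(ids[j]), j) for j in range(n) if j != i]
        cand.sort()
        out.append([j for _, _, j in cand[:k]])
    return np.array(out)


def brute_refine(coords, ids, labels, k):
    """Oracle majority vote with the conservative tie policy."""
    nb = brute_knn(coords, ids, k)
    refined = []
    for i in range(len(ids)):
        votes = pd.Series([labels[j] for j in nb[i]]).value_counts()
        tied = sorted(votes[votes == votes.max()].index)
        refined.append(labels[i] if labels[i] in tied else tied[0])
    return np.asarray(refined, dtype=object)


def test_knn_collinear_points():
    emb = _embedding([[0, 0], [1, 0], [10, 0]])
    idx = knn_index(emb, k=1)
    assert idx.indices[1, 0] == 0  # middle point's neighbor is nearer endpoint


def test_knn_unit_square_edge_adjacent():
    emb = _embedding([[0, 0], [1, 0], [1, 1], [0, 1]])
    idx = knn_index(emb, k=2)
    expected = {0: {1, 3}, 1: {0, 2}, 2: {1, 3}, 3: {0, 2}}
    for i, exp in expected.items():
        assert set(idx.indices[i]) == exp


def test_knn_matches_bruteforce_oracle(rng):
    coords = rng.normal(size=(200, 6))
    ids = [f"c{i:03d}" for i in range(200)]
    emb = _embedding(coords, ids)
    idx = knn_index(emb, k=25)
    assert np.array_equal(idx.indices, brute_knn(coords, ids, 25))


def test_knn_k_too_large_raises():
    emb = _embedding(np.eye(3))
    with pytest.raises(ValueError):
        knn_index(emb, k=3)


def test_refine_fixed_point_on_uniform_labels(rng):
    emb = _embedding(rng.normal(size=(40, 3)))
    labels = LabelSet(cell_ids=emb.cell_ids, labels=np.array(["A"] * 40, dtype=object))
    out = refine_labels(emb, labels, k=5)
    assert np.array_equal(out.labels, labels.labels)
    assert np.array_equal(out.refined_from, labels.labels)


def test_refine_unanimous_vote_relabels_with_confidence_one(rng):
    coords = rng.normal(0, 0.1, size=(26, 2))
    labels = np.array(["A"] * 26, dtype=object)
    labels[0] = "B"  # lone dissenter inside a tight cluster
    emb = _embedding(coords)
    out = refine_labels(emb, LabelSet(cell_ids=emb.cell_ids, labels=labels), k=25)
    assert out.labels[0] == "A"
    assert out.confidence[0] == 1.0
    assert out.refined_from[0] == "B"


def test_refine_matches_oracle_and_improves_noisy_labels(rng):
    """8% planted label noise on separated clusters: refinement equals the
    brute-force oracle exactly and strictly reduces disagreement with truth."""
    centers = np.array([[0, 0, 0], [12, 0, 0], [0, 12, 0]], dtype=float)
    truth, coords = [], []
    for c, name in zip(centers, "ABC"):
        coords.append(rng.normal(0, 1, size=(34, 3)) + c)
        truth += [name] * 34
    coords = np.vstack(coords)[:100]
    truth = np.asarray(truth[:100], dtype=object)
    noisy = truth.copy()
    flip = rng.choice(100, size=8, replace=False)
    for i in flip:
        noisy[i] = {"A": "B", "B": "C", "C": "A"}[noisy[i]]
    emb = _embedding(coords)
    out = refine_labels(emb, LabelSet(cell_ids=emb.cell_ids, labels=noisy), k=25)
    oracle = brute_refine(coords, emb.cell_ids, noisy, 25)
    assert np.array_equal(out.labels, oracle)
    assert (out.labels != truth).sum() < (noisy != truth).sum()


def test_refine_tie_prefers_original_label():
    # cell 0 at the midpoint of one "A" and one "B" cell: 1-1 tie at k=2
    emb = _embedding([[0.0, 0.0], [-1.0, 0.0], [1.0, 0.0]])
    labels = LabelSet(cell_ids=emb.cell_ids, labels=np.array(["B", "A", "B"], dtype=object))
    out = refine_labels(emb, labels, k=2)
    assert out.labels[0] == "B"  # original kept among tied modes


def test_refine_missing_labels_policy(rng):
    emb = _embedding(rng.normal(size=(30, 2)))
    labels = np.array(["A"] * 30, dtype=object)
    labels[4] = None
    ls = LabelSet(cell_ids=emb.cell_ids, labels=labels)
    with pytest.raises(ValueError):
        refine_labels(emb, ls, k=5)
    out = refine_labels(emb, ls, k=5, allow_missing=True)
    assert out.labels[4] is None  # left unrefined
    assert np.all(out.labels[np.arange(30) != 4] == "A")


def test_purity_perfect_separation_is_identity(rng):
    coords = np.vstack([rng.normal(0, 0.5, size=(50, 2)),
                        rng.normal(0, 0.5, size=(50, 2)) + 1000.0])
    labels = LabelSet(
        cell_ids=np.array([f"c{i:03d}" for i in range(100)], dtype=object),
        labels=np.array(["L"] * 50 + ["R"] * 50, dtype=object),
    )
    pm = neighbor_purity(_embedding(coords, labels.cell_ids), labels, k=30)
    assert np.allclose(pm.values.to_numpy(), 100 * np.eye(2))
    assert pm.k_used == 30


def test_purity_matches_bruteforce_oracle(rng):
    coords = rng.normal(size=(300, 4))
    ids = [f"c{i:03d}" for i in range(300)]
    labels = rng.choice(["A", "B", "C"], size=300).astype(object)
    emb = _embedding(coords, ids)
    pm = neighbor_purity(emb, LabelSet(cell_ids=emb.cell_ids, labels=labels), k=40)
    nb = brute_knn(coords, ids, 40)
    for a in "ABC":
        cells = np.flatnonzero(labels == a)
        for b in "ABC":
            expect = np.mean([(labels[nb[i]] == b).mean() * 100 for i in cells])
            assert abs(pm.values.loc[a, b] - expect) < 1e-9


def test_purity_rigid_motion_invariance(rng):
    coords = rng.normal(size=(150, 3))
    labels = LabelSet(
        cell_ids=np.array([f"c{i:03d}" for i in range(150)], dtype=object),
        labels=rng.choice(["A", "B"], size=150).astype(object),
    )
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    pm1 = neighbor_purity(_embedding(coords, labels.cell_ids), labels, k=20)
    pm2 = neighbor_purity(_embedding(coords @ Q + 5.0, labels.cell_ids), labels, k=20)
    assert np.allclose(pm1.values.to_numpy(), pm2.values.to_numpy(), atol=1e-9)


def test_purity_drops_empty_class_with_warning(rng, caplog):
    emb = _embedding(rng.normal(size=(30, 2)))
    labels = LabelSet(cell_ids=emb.cell_ids, labels=np.array(["A"] * 30, dtype=object),
                      vocabulary=("A", "ghost"))
    with caplog.at_level("WARNING"):
        pm = neighbor_purity(emb, labels, k=10)
    assert "ghost" not in pm.values.index
    assert "ghost" in pm.values.columns
    assert any("ghost" in r.message for r in caplog.records)


def test_batch_report_translated_batches_unmixed(rng):
    coords = rng.normal(size=(120, 3))
    coords[60:] += 500.0
    ids = np.array([f"c{i:03d}" for i in range(120)], dtype=object)
    batch = LabelSet(cell_ids=ids, labels=np.array(["b0"] * 60 + ["b1"] * 60, dtype=object))
    state = LabelSet(cell_ids=ids, labels=rng.choice(["s0", "s1"], 120).astype(object))
    rep = batch_mixing_report(_embedding(coords, ids), batch, state, k=30)
    diag = [rep["purity_by_batch"].values.loc[b, b] for b in ("b0", "b1")]
    assert np.allclose(diag, 100.0)
    assert rep["batch_mixing_score"] == 0.0


def test_batch_report_ideal_embedding_well_mixed(small_sim):
    """On the noise-free factor embedding with balanced batches, each batch's
    neighbor composition approaches the global batch proportions."""
    from fibroharmony.datatypes import labels_from_obs

    _, adata, emb, _ = small_sim
    rep = batch_mixing_report(
        emb, labels_from_obs(adata, "batch"), labels_from_obs(adata, "population"), k=100
    )
    diag = [rep["purity_by_batch"].values.loc[b, b] for b in ("batch0", "batch1")]
    assert np.all(np.abs(np.array(diag) - 50.0) < 6.0)
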