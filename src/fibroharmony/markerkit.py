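"""Marker detection, cross-dataset population matching, and gene-set scoring.

Operations:

* :func:`find_markers` — per-gene two-group marker test (default Wilcoxon
  rank-sum; pluggable) with Bonferroni adjustment and the adjusted-P < 1e-5
  / log2 fold change > 0.5 significance filter.
* :func:`jaccard_match` / :func:`fisher_overlap_test` — Jaccard
  coefficients and one-sided Fisher (hypergeometric) enrichment for
  matching populations across datasets or species through marker-gene
  overlap.
* :func:`module_score` — binned-control gene-set score: mean expression of
  the set minus the mean of expression-bin-matched control genes.
* :func:`regulon_activity` — weighted-mean transcription-factor regulon
  activity normalized against gene-label permutations (times=100,
  minsize=5), with a per-population summary helper.
* :func:`fold_change_correlation` — Pearson correlation of log2 fold
  changes across two contrasts over genes significant in either.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

from .datatypes import (
    LabelSet,
    OverlapResult,
    log_normalize,
    validate_marker_table,
    validate_regulon_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "find_markers",
    "jaccard_match",
    "fisher_overlap_test",
    "module_score",
    "regulon_activity",
    "activity_by_population",
    "fold_change_correlation",
    "wilcoxon_test",
    "ttest_test",
]


def _dense_layer(adata: AnnData, layer: str) -> np.ndarray:
    log_normalize(adata)
    X = adata.layers[layer] if layer in adata.layers else adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def wilcoxon_test(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per gene (column)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x_in, x_out, axis=0, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    # all-tied genes yield NaN under the normal approximation: no evidence
    return np.where(np.isnan(p), 1.0, p)


def ttest_test(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Welch t-test p-values per gene; alternative pluggable backend."""
    p = stats.ttest_ind(x_in, x_out, axis=0, equal_var=False).pvalue
    return np.where(np.isnan(np.asarray(p, dtype=float)), 1.0, p)


_TESTS: dict[str, Callable] = {"wilcoxon": wilcoxon_test, "ttest": ttest_test}


def find_markers(
    adata: AnnData,
    labels: LabelSet | str,
    target: str,
    reference: str | None = None,
    min_frac: float = 0.0,
    alpha_adj: float = 1e-5,
    lfc_min: float = 0.5,
    test: str | Callable = "wilcoxon",
    pseudocount: float = 1.0,
    layer: str = "lognorm",
    filter_significant: bool = True,
) -> pd.DataFrame:
    """Marker genes of ``target`` cells versus the rest (or a named reference).

    Each gene gets a two-group test p-value (Bonferroni-adjusted over all
    genes tested), a log2 fold change on the normalized scale
    ``log2((mean_in + pc) / (mean_out + pc))`` with ``pc`` applied on the
    de-logged (counts-per-10k) scale, and in/out expressing fractions.
    With ``filter_significant`` (default) only rows with
    ``p_adj < alpha_adj`` and ``log2_fold_change > lfc_min`` and
    ``frac_expr_in >= min_frac`` are returned; otherwise all genes are
    returned with a boolean ``significant`` column (needed for
    :func:`fold_change_correlation`).
    """
    if isinstance(labels, str):
        lab = adata.obs[labels].to_numpy(dtype=object)
    else:
        if not np.array_equal(labels.cell_ids, np.asarray(adata.obs_names, dtype=object)):
            raise ValueError("label set does not align with expression matrix cells")
        lab = labels.labels
    in_mask = lab == target
    out_mask = (lab == reference) if reference is not None else ~in_mask
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise ValueError(
            f"need >= 3 cells per group; got {int(in_mask.sum())} target, {int(out_mask.sum())} reference"
        )
    X = _dense_layer(adata, layer)
    x_in, x_out = X[in_mask], X[out_mask]

    test_fn = _TESTS[test] if isinstance(test, str) else test
    p_raw = np.clip(np.asarray(test_fn(x_in, x_out), dtype=float), 0.0, 1.0)
    n_tested = X.shape[1]
    p_adj = np.minimum(1.0, p_raw * n_tested)

    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    frac_in = (x_in > 0).mean(axis=0)
    frac_out = (x_out > 0).mean(axis=0)

    df = pd.DataFrame(
        {
            "population": target,
            "gene": np.asarray(adata.var_names, dtype=object),
            "log2_fold_change": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "frac_expr_in": frac_in,
            "frac_expr_out": frac_out,
        }
    )
    sig = (df["p_adj"] < alpha_adj) & (df["log2_fold_change"] > lfc_min) & (df["frac_expr_in"] >= min_frac)
    if filter_significant:
        df = df[sig].reset_index(drop=True)
    else:
        df = df.assign(significant=sig.to_numpy())
    return validate_marker_table(df)


def fisher_overlap_test(n_intersect, n_a: int, n_b: int, n_universe: int):
    """One-sided enrichment P(X >= n_intersect), X ~ Hypergeom(N, n_a, n_b).

    ``n_intersect`` may be an array (vectorized over overlap counts);
    scalars return a float.
    """
    k = np.asarray(n_intersect)
    if not (0 <= max(n_a, n_b) <= n_universe) or min(n_a, n_b) < 0:
        raise ValueError(f"inconsistent counts: a={n_a}, b={n_b}, universe={n_universe}")
    if np.any(k > min(n_a, n_b)) or np.any(k < 0):
        raise ValueError(
            f"inconsistent counts: intersect={n_intersect}, a={n_a}, b={n_b}, universe={n_universe}"
        )
    if np.any(k < n_a + n_b - n_universe):
        raise ValueError("n_intersect below the feasible minimum for these counts")
    p = stats.hypergeom.sf(k - 1, n_universe, n_a, n_b)
    return float(p) if np.isscalar(n_intersect) else np.asarray(p, dtype=float)


def _normalize_symbol(g: str) -> str:
    return str(g).upper()


def _map_genes(genes: Sequence[str], ortholog_map) -> set:
    """Map gene symbols into the shared comparison namespace.

    Default (``ortholog_map=None``) is case-normalized symbol matching
    (mouse Title-case vs human UPPER-case). An explicit mapping may be a
    dict/Series (gene -> shared symbol); unmapped genes are dropped.
    """
    if ortholog_map is None:
        return {_normalize_symbol(g) for g in genes}
    if isinstance(ortholog_map, pd.Series):
        ortholog_map = ortholog_map.to_dict()
    return {ortholog_map[g] for g in genes if g in ortholog_map}


def jaccard_match(
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    ortholog_map=None,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Jaccard + Fisher matching of populations across two marker tables.

    Marker sets are mapped through ``ortholog_map`` (default: upper-cased
    symbol matching) and restricted to the shared universe of genes tested
    in both datasets. ``top_n`` optionally caps each population's set to
    its ``top_n`` markers by adjusted p-value. Returns one row per
    (population_a, population_b) pair with jaccard, overlap counts, and
    the one-sided Fisher p over the shared universe.
    """
    validate_marker_table(markers_a)
    validate_marker_table(markers_b)
    universe = _map_genes(universe_a, ortholog_map) & _map_genes(universe_b, ortholog_map)
    if not universe:
        raise ValueError("empty shared gene universe after ortholog mapping")

    def _sets(markers: pd.DataFrame) -> dict:
        out = {}
        for pop, grp in markers.groupby("population", sort=True):
            if top_n is not None:
                grp = grp.nsmallest(top_n, "p_adj")
            mapped = _map_genes(grp["gene"], ortholog_map) & universe
            if not mapped:
                raise ValueError(f"population {pop!r}: no markers left after ortholog mapping")
            out[pop] = mapped
        return out

    sets_a, sets_b = _sets(markers_a), _sets(markers_b)
    rows = []
    for pa, ga in sets_a.items():
        for pb, gb in sets_b.items():
            inter = len(ga & gb)
            union = len(ga | gb)
            res = OverlapResult(
                jaccard=0.0 if union == 0 else inter / union,
                n_intersect=inter,
                n_a=len(ga),
                n_b=len(gb),
                n_universe=len(universe),
                fisher_p=fisher_overlap_test(inter, len(ga), len(gb), len(universe)),
            )
            rows.append(
                {
                    "population_a": pa, "population_b": pb, "jaccard": res.jaccard,
                    "n_intersect": res.n_intersect, "n_a": res.n_a, "n_b": res.n_b,
                    "n_universe": res.n_universe, "fisher_p": res.fisher_p,
                }
            )
    return pd.DataFrame(rows)


def module_score(
    adata: AnnData,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = "lognorm",
) -> pd.Series:
    """Binned-control gene-set score per cell.

    Genes are binned into ``n_bins`` equal-size bins of dataset-average
    expression; for every set gene, up to ``n_ctrl`` control genes are
    sampled (without replacement) from its bin, and the per-cell score is
    ``mean(expr over set) - mean(expr over the pooled control set)``.
    Controls are sampled once per call from ``seed``.
    """
    present = [g for g in gene_set if g in adata.var_names]
    if len(gene_set) == 0 or len(present) == 0:
        raise ValueError("gene_set is empty or entirely absent from the matrix")
    X = _dense_layer(adata, layer)
    genes = np.asarray(adata.var_names, dtype=object)
    gidx = {g: i for i, g in enumerate(genes)}
    set_idx = np.array([gidx[g] for g in present])

    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.floor(np.arange(len(genes)) * n_bins / len(genes)).astype(int)

    rng = np.random.default_rng(seed)
    ctrl: set = set()
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl))

    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="module_score")


def regulon_activity(
    adata: AnnData,
    regulons: pd.DataFrame,
    times: int = 100,
    minsize: int = 5,
    seed: int = 0,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Permutation-normalized weighted-mean regulon activity (cells x TFs).

    The raw statistic per cell is the weighted sum of target-gene
    expression. Each of ``times`` rounds permutes the gene labels of the
    expression matrix and recomputes it; the reported activity is the
    z-score of the observed statistic against that permutation null.
    Regulons with fewer than ``minsize`` targets present are dropped with
    a warning; a zero permutation SD yields activity 0 with a warning.
    """
    validate_regulon_table(regulons)
    X = _dense_layer(adata, layer)
    genes = np.asarray(adata.var_names, dtype=object)
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    tfs, cols = [], []
    for tf, grp in regulons.groupby("tf", sort=True):
        present = grp[grp["target"].isin(gidx)]
        if len(present) < minsize:
            logger.warning("regulon %r has %d targets present (< minsize=%d); dropped", tf, len(present), minsize)
            continue
        w = np.zeros(n_genes)
        w[[gidx[t] for t in present["target"]]] = present["weight"].to_numpy(dtype=float)
        tfs.append(tf)
        cols.append(w)
    if not tfs:
        raise ValueError("no regulon passes the minsize filter")
    A = np.column_stack(cols)                       # genes x tfs

    raw = X @ A                                     # cells x tfs
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(raw)
    acc2 = np.zeros_like(raw)
    for _ in range(times):
        perm = rng.permutation(n_genes)
        r = X @ A[perm]
        acc += r
        acc2 += r * r
    mean = acc / times
    var = (acc2 - times * mean * mean) / (times - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d (cell, regulon) entries had zero permutation sd; activity set to 0", int(zero_sd.sum()))
    z = np.where(zero_sd, 0.0, (raw - mean) / np.where(zero_sd, 1.0, sd))
    return pd.DataFrame(z, index=adata.obs_names, columns=tfs)


def activity_by_population(activity: pd.DataFrame, labels: LabelSet | Mapping) -> pd.DataFrame:
    """Mean normalized activity per population (populations x TFs)."""
    if isinstance(labels, LabelSet):
        s = pd.Series(labels.labels, index=labels.cell_ids)
    else:
        s = pd.Series(labels)
    return activity.groupby(s.reindex(activity.index)).mean()


def fold_change_correlation(
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    alpha_adj: float = 1e-5,
    lfc_min: float = 0.5,
) -> float:
    """Pearson correlation of log2 fold changes across two contrasts.

    The gene list is the union of genes significant in either table;
    fold-change values come from each table's own (unfiltered) rows — pass
    tables produced with ``filter_significant=False`` so non-significant
    genes carry a measured, not imputed, fold change. Genes absent from
    one table are dropped with a warning.
    """
    def _prep(df: pd.DataFrame) -> tuple[pd.Series, set]:
        validate_marker_table(df)
        if "significant" in df.columns:
            sig = df.loc[df["significant"], "gene"]
        else:
            sig = df.loc[
                (df["p_adj"] < alpha_adj) & (df["log2_fold_change"] > lfc_min), "gene"
            ]
        return df.set_index("gene")["log2_fold_change"], set(sig)

    fc_a, sig_a = _prep(markers_a)
    fc_b, sig_b = _prep(markers_b)
    union = sorted(sig_a | sig_b)
    shared = [g for g in union if g in fc_a.index and g in fc_b.index]
    if len(shared) < len(union):
        logger.warning("%d significant genes missing from one table; dropped", len(union) - len(shared))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes with fold changes; got {len(shared)}")
    r, _ = stats.pearsonr(fc_a.loc[shared], fc_b.loc[shared])
    return float(r)
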