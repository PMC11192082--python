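"""Marker thresholds, overlap statistics, module scores, regulon activity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from fibroharmony.datatypes import labels_from_obs
from fibroharmony.markerkit import (
    find_markers,
    fisher_overlap_test,
    fold_change_correlation,
    jaccard_match,
    module_score,
    regulon_activity,
)
from fibroharmony.syndata import SimConfig, generate_multibatch_counts


def hypergeom_tail(k, na, nb, N):
    """Oracle: direct summation of the hypergeometric pmf for P(X >= k)."""
    total = comb(N, nb, exact=True)
    return sum(
        comb(na, x, exact=True) * comb(N - na, nb - x, exact=True) for x in range(k, min(na, nb) + 1)
    ) / total


class TestFisher:
    def test_zero_intersection_gives_one(self):
        assert fisher_overlap_test(0, 5, 5, 20) == 1.0

    def test_matches_tail_summation_example(self):
        assert fisher_overlap_test(3, 5, 5, 20) == pytest.approx(hypergeom_tail(3, 5, 5, 20), rel=1e-12)

    def test_maximal_overlap_matches_enumeration(self):
        assert fisher_overlap_test(4, 4, 9, 20) == pytest.approx(hypergeom_tail(4, 4, 9, 20), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_enumeration_random_counts(self, data):
        N = data.draw(st.integers(2, 60))
        na = data.draw(st.integers(1, N))
        nb = data.draw(st.integers(1, N))
        lo = max(0, na + nb - N)
        k = data.draw(st.integers(lo, min(na, nb)))
        assert fisher_overlap_test(k, na, nb, N) == pytest.approx(
            hypergeom_tail(k, na, nb, N), rel=1e-9, abs=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap_test(6, 5, 5, 20)
        with pytest.raises(ValueError):
            fisher_overlap_test(0, 25, 5, 20)


def _marker_table(pop_genes: dict) -> pd.DataFrame:
    rows = []
    for pop, genes in pop_genes.items():
        for g in genes:
            rows.append({"population": pop, "gene": g, "log2_fold_change": 1.0,
                         "p_raw": 1e-9, "p_adj": 1e-7, "frac_expr_in": 0.8, "frac_expr_out": 0.1})
    return pd.DataFrame(rows)


class TestJaccardMatch:
    universe = [f"G{i}" for i in range(2000)]

    def test_identical_sets_jaccard_one(self):
        t = _marker_table({"P": [f"G{i}" for i in range(30)]})
        res = jaccard_match(t, t, self.universe, self.universe)
        assert res["jaccard"].iloc[0] == 1.0

    def test_disjoint_sets_jaccard_zero(self):
        a = _marker_table({"P": [f"G{i}" for i in range(30)]})
        b = _marker_table({"Q": [f"G{i}" for i in range(40, 80)]})
        res = jaccard_match(a, b, self.universe, self.universe)
        assert res["jaccard"].iloc[0] == 0.0
        assert res["fisher_p"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_overlap_example_with_fisher_oracle(self):
        """|A|=30, |B|=40, overlap 20, universe 2000: jaccard 0.4 and the
        Fisher p equals the exhaustive hypergeometric tail sum."""
        a = _marker_table({"A": [f"G{i}" for i in range(30)]})
        b = _marker_table({"B": [f"G{i}" for i in range(10, 50)]})
        res = jaccard_match(a, b, self.universe, self.universe)
        assert res["jaccard"].iloc[0] == pytest.approx(0.4)
        assert res["n_intersect"].iloc[0] == 20
        assert res["fisher_p"].iloc[0] == pytest.approx(hypergeom_tail(20, 30, 40, 2000), rel=1e-9)

    def test_symmetry_under_swap(self):
        a = _marker_table({"A1": [f"G{i}" for i in range(25)], "A2": [f"G{i}" for i in range(50, 60)]})
        b = _marker_table({"B1": [f"G{i}" for i in range(15, 40)]})
        ab = jaccard_match(a, b, self.universe, self.universe)
        ba = jaccard_match(b, a, self.universe, self.universe)
        for _, r in ab.iterrows():
            mirror = ba[(ba["population_a"] == r["population_b"]) & (ba["population_b"] == r["population_a"])]
            assert mirror["jaccard"].iloc[0] == r["jaccard"]
            assert mirror["fisher_p"].iloc[0] == r["fisher_p"]

    def test_case_normalized_ortholog_default(self):
        mouse = _marker_table({"F-SH": ["Comp", "Sfrp2", "Cthrc1"]})
        human = _marker_table({"H-3": ["COMP", "SFRP2", "ACTA2"]})
        res = jaccard_match(mouse, human, ["Comp", "Sfrp2", "Cthrc1", "Acta2"],
                            ["COMP", "SFRP2", "ACTA2", "CTHRC1"])
        assert res["n_intersect"].iloc[0] == 2
        assert res["jaccard"].iloc[0] == pytest.approx(0.5)

    def test_empty_universe_rejected(self):
        a = _marker_table({"P": ["G1"]})
        with pytest.raises(ValueError):
            jaccard_match(a, a, ["G1"], ["ZZZ"])


class TestFindMarkers:
    def test_planted_markers_found_null_genes_excluded(self, small_sim, small_labels):
        _, adata, _, truth = small_sim
        found = set(find_markers(adata, small_labels, "pop0")["gene"])
        planted = set(truth.marker_truth["pop0"])
        assert len(found & planted) / len(planted) >= 0.8
        assert len(found & planted) / len(found) >= 0.9

    def test_identical_gene_gets_zero_lfc_and_excluded(self, rng):
        """A gene with identical expression in both groups: log2FC exactly 0,
        never reported as a marker."""
        from anndata import AnnData
        import scipy.sparse as sp
        from fibroharmony.datatypes import LabelSet

        n, g = 60, 40
        layer = rng.normal(1.0, 0.2, size=(n, g)).clip(min=0)
        layer[:, 0] = np.tile(layer[: n // 2, 0], 2)  # gene 0 identical across groups
        adata = AnnData(X=sp.csr_matrix(np.zeros((n, g))),
                        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
                        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]))
        adata.layers["lognorm"] = layer
        labels = LabelSet(cell_ids=np.asarray(adata.obs_names, dtype=object),
                          labels=np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object))
        full = find_markers(adata, labels, "A", filter_significant=False)
        row = full[full["gene"] == "g0"].iloc[0]
        assert row["log2_fold_change"] == 0.0
        assert not row["significant"]

    def test_too_few_cells_rejected(self, small_sim):
        _, adata, _, _ = small_sim
        labels = labels_from_obs(adata, "population")
        bad = labels.labels.copy()
        bad[bad == "pop0"] = "pop1"
        bad[:2] = "pop0"
        from fibroharmony.datatypes import LabelSet
        with pytest.raises(ValueError, match="3 cells"):
            find_markers(adata, LabelSet(cell_ids=labels.cell_ids, labels=bad), "pop0")

    def test_named_reference_group(self, small_sim, small_labels):
        _, adata, _, truth = small_sim
        t = find_markers(adata, small_labels, "pop0", reference="pop2")
        assert set(truth.marker_truth["pop0"]) & set(t["gene"])


class TestModuleScore:
    def test_all_genes_score_exactly_zero(self, small_sim):
        _, adata, _, _ = small_sim
        s = module_score(adata, list(adata.var_names), seed=0)
        assert np.abs(s).max() <= 1e-12

    def test_recovers_planted_shift(self, rng):
        """A +delta log-shift of the set genes in half the cells shows up as
        ~delta difference in mean module score between the halves."""
        from anndata import AnnData
        import scipy.sparse as sp

        n_cells, n_genes, delta = 300, 600, 0.8
        base = rng.uniform(0.5, 2.5, size=n_genes)  # spread so bins mix set and background
        X = (base[None, :] + rng.normal(0, 0.3, size=(n_cells, n_genes))).clip(min=0)
        genes = [f"g{i:03d}" for i in range(n_genes)]
        gene_set = genes[:30]
        X[: n_cells // 2, :30] += delta
        adata = AnnData(X=sp.csr_matrix(np.zeros_like(X)),
                        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
                        var=pd.DataFrame(index=genes))
        adata.layers["lognorm"] = X
        s = module_score(adata, gene_set, seed=0)
        diff = s.iloc[: n_cells // 2].mean() - s.iloc[n_cells // 2:].mean()
        assert diff == pytest.approx(delta, abs=0.1)

    def test_control_resampling_stability(self, small_sim):
        _, adata, _, truth = small_sim
        genes = list(truth.marker_truth["pop0"])
        s1 = module_score(adata, genes, seed=1)
        s2 = module_score(adata, genes, seed=2)
        assert s1.corr(s2, method="spearman") >= 0.95

    def test_empty_or_absent_set_rejected(self, small_sim):
        _, adata, _, _ = small_sim
        with pytest.raises(ValueError):
            module_score(adata, [])
        with pytest.raises(ValueError):
            module_score(adata, ["not_a_gene"])


class TestRegulonActivity:
    def test_undersized_regulon_dropped(self, small_sim, caplog):
        _, adata, _, _ = small_sim
        reg = pd.DataFrame({
            "tf": ["small"] * 4 + ["big"] * 6,
            "target": list(adata.var_names[:4]) + list(adata.var_names[10:16]),
            "weight": 1.0,
        })
        with caplog.at_level("WARNING"):
            act = regulon_activity(adata, reg, times=20, seed=0)
        assert list(act.columns) == ["big"]
        assert any("small" in r.message for r in caplog.records)

    def test_zero_weights_give_zero_activity(self, small_sim, caplog):
        _, adata, _, _ = small_sim
        reg = pd.DataFrame({"tf": "z", "target": adata.var_names[:6], "weight": 0.0})
        with caplog.at_level("WARNING"):
            act = regulon_activity(adata, reg, times=20, seed=0)
        assert np.all(act.to_numpy() == 0.0)

    def test_planted_regulon_peaks_in_its_population(self, small_sim):
        _, adata, _, truth = small_sim
        from fibroharmony.markerkit import activity_by_population

        rng = np.random.default_rng(3)
        rows = [{"tf": "TF_pop0", "target": g, "weight": 1.0} for g in truth.marker_truth["pop0"]]
        for j in range(3):
            for g in rng.choice(adata.var_names, 10, replace=False):
                rows.append({"tf": f"null{j}", "target": g, "weight": float(rng.choice([-1, 1]))})
        act = regulon_activity(adata, pd.DataFrame(rows), times=100, seed=3)
        summary = activity_by_population(act, labels_from_obs(adata, "population"))
        assert summary["TF_pop0"].idxmax() == "pop0"
        assert summary.loc["pop0", "TF_pop0"] > summary[[c for c in act if c != "TF_pop0"]].to_numpy().max()


class TestFoldChangeCorrelation:
    def _table(self, lfc, sig=None):
        n = len(lfc)
        return pd.DataFrame({
            "population": "P", "gene": [f"G{i}" for i in range(n)],
            "log2_fold_change": lfc, "p_raw": 1e-9, "p_adj": 1e-7,
            "frac_expr_in": 0.5, "frac_expr_out": 0.1,
            "significant": np.ones(n, bool) if sig is None else sig,
        })

    def test_self_correlation_is_one(self, rng):
        t = self._table(rng.normal(1, 0.5, 50))
        assert fold_change_correlation(t, t) == pytest.approx(1.0)

    def test_negated_correlation_is_minus_one(self, rng):
        lfc = rng.normal(1, 0.5, 50)
        a, b = self._table(lfc), self._table(-lfc)
        assert fold_change_correlation(a, b) == pytest.approx(-1.0)

    def test_recovers_planted_correlation(self, rng):
        """Effect sizes drawn with correlation 0.8 are estimated within +-0.1
        at 200 genes."""
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        fc = rng.multivariate_normal([1.0, 1.0], cov, size=200)
        r = fold_change_correlation(self._table(fc[:, 0]), self._table(fc[:, 1]))
        assert r == pytest.approx(0.8, abs=0.1)

    def test_too_few_shared_genes_rejected(self):
        a, b = self._table(np.ones(2)), self._table(np.ones(2))
        with pytest.raises(ValueError):
            fold_change_correlation(a, b)
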