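"""Specificity scoring: filters, normalization, ranking, Jaccard."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celliability import specificity as sp


def make_ann(sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    for cluster, n in sizes.items():
        for i in range(n):
            rows.append((f"{cluster}_c{i}", cluster, "D0", "adult"))
    return pd.DataFrame(rows, columns=["cell_id", "cluster", "donor", "stage"])


class TestFilterClusters:
    def test_two_tiny_clusters_removed_from_86(self):
        sizes = {f"pop{i}": 20 for i in range(84)}
        sizes["Oligo-6"] = 7
        sizes["Oligo-7"] = 3
        out = sp.filter_clusters(make_ann(sizes), min_cells=10)
        assert out["cluster"].nunique() == 84
        assert not {"Oligo-6", "Oligo-7"} & set(out["cluster"])

    def test_boundary_cluster_of_exactly_min_cells_kept(self):
        out = sp.filter_clusters(make_ann({"a": 10, "b": 9}), min_cells=10)
        assert set(out["cluster"]) == {"a"}

    def test_min_cells_one_is_identity(self):
        ann = make_ann({"a": 3, "b": 1})
        assert sp.filter_clusters(ann, min_cells=1).equals(ann)

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError, match="no clusters"):
            sp.filter_clusters(make_ann({"a": 2}), min_cells=10)


def _gene_row(gid, chrom, start, end, biotype="protein_coding"):
    return {"gene_id": gid, "chrom": chrom, "start": start, "end": end,
            "strand": "+", "biotype": biotype}


class TestFilterGenes:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(0)
        ann = make_ann({"a": 30, "b": 30})
        genes = pd.DataFrame([
            _gene_row("g_auto", "1", 1000, 2000),
            _gene_row("g_x", "X", 1000, 2000),
            _gene_row("g_mhc_inside", "6", 26_000_000, 26_100_000),
            _gene_row("g_mhc_overlap", "6", 24_999_000, 25_000_500),
            _gene_row("g_mhc_out", "6", 24_000_000, 24_500_000),
            _gene_row("g_sparse", "2", 5000, 6000),
            _gene_row("g_base", "2", 9000, 9500),
        ])
        counts = pd.DataFrame(
            0, index=genes["gene_id"], columns=ann["cell_id"], dtype=int
        )
        in_a = (ann["cluster"] == "a").to_numpy()
        for g in ["g_auto", "g_mhc_inside", "g_mhc_overlap", "g_mhc_out", "g_x"]:
            counts.loc[g, :] = rng.poisson(1, 60)
            counts.loc[g, in_a] += rng.poisson(8, 30)  # informative
        counts.loc["g_sparse", counts.columns[:5]] = 3  # < 10 cells
        counts.loc["g_base", :] = rng.poisson(5, 60) + 1  # keeps totals positive
        counts.loc["g_base", in_a] += rng.poisson(4, 30)
        return counts, genes, ann

    def test_filters_apply(self, setup):
        counts, genes, ann = setup
        out = sp.filter_genes(counts, genes, ann)
        kept = set(out.index)
        assert "g_x" not in kept  # non-autosomal
        assert "g_mhc_inside" not in kept
        assert "g_mhc_overlap" not in kept  # any overlap with closed interval
        assert "g_mhc_out" in kept
        assert "g_sparse" not in kept  # expressed in < 10 cells
        assert "g_auto" in kept

    def test_gene_identical_across_types_is_uninformative(self):
        # balanced design: every cell has the same total count, so the
        # flat gene is exactly constant after normalization
        ann = make_ann({"a": 15, "b": 15})
        in_a = (ann["cluster"] == "a").to_numpy()
        counts = pd.DataFrame(
            0, index=["g_flat", "g_up", "g_down"], columns=ann["cell_id"], dtype=int
        )
        counts.loc["g_flat"] = 5
        counts.loc["g_up"] = np.where(in_a, 8, 2)
        counts.loc["g_down"] = np.where(in_a, 2, 8)
        genes = pd.DataFrame([
            _gene_row("g_flat", "1", 1000, 2000),
            _gene_row("g_up", "1", 3000, 4000),
            _gene_row("g_down", "1", 5000, 6000),
        ])
        out = sp.filter_genes(counts, genes, ann)
        assert set(out.index) == {"g_up", "g_down"}

    def test_unknown_chromosome_names_gene(self, setup):
        counts, genes, ann = setup
        genes.loc[genes["gene_id"] == "g_auto", "chrom"] = "weird"
        with pytest.raises(ValueError, match="g_auto"):
            sp.filter_genes(counts, genes, ann)

    def test_missing_gene_model_is_error(self, setup):
        counts, genes, ann = setup
        with pytest.raises(ValueError, match="missing"):
            sp.filter_genes(counts, genes.iloc[1:], ann)


class TestNormalize:
    def test_log_cp10k_zero_count_maps_to_zero(self):
        counts = pd.DataFrame([[0, 4], [10, 6]], index=["g1", "g2"],
                              columns=["c1", "c2"])
        out = sp.normalize(counts, "log_cp10k")
        assert out.loc["g1", "c1"] == 0.0
        assert out.loc["g2", "c1"] == pytest.approx(math.log1p(1e4))

    def test_log_cp10k_cell_scaling_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(5, (20, 4)) + 1)
        doubled = counts.copy()
        doubled[0] = counts[0] * 2
        a = sp.normalize(counts, "log_cp10k")
        b = sp.normalize(doubled, "log_cp10k")
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_pearson_residual_hand_oracle(self):
        # 3 genes x 2 cells; mu_gc = gene_total/overall_total * cell_total
        counts = pd.DataFrame([[2, 0], [1, 3], [1, 1]], index=list("abc"),
                              columns=["c1", "c2"])
        theta = 100.0
        x = counts.to_numpy(float)
        mu = np.outer(x.sum(1) / x.sum(), x.sum(0))
        expected = np.clip((x - mu) / np.sqrt(mu + mu * mu / theta),
                           -np.sqrt(2), np.sqrt(2))
        out = sp.normalize(counts, "pearson_residual", theta=theta)
        np.testing.assert_allclose(out.to_numpy(), expected, rtol=1e-12)

    def test_zero_total_cell_is_error(self):
        counts = pd.DataFrame([[0, 1]], index=["g"], columns=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            sp.normalize(counts)


class TestSpecificityMatrix:
    def _spec(self, mat, groups):
        genes = [f"g{i}" for i in range(mat.shape[0])]
        cells = [f"c{i}" for i in range(mat.shape[1])]
        ann = pd.DataFrame({"cell_id": cells, "cluster": groups})
        return sp.specificity_matrix(
            pd.DataFrame(mat, index=genes, columns=cells), ann
        )

    def test_exclusive_and_proportional_rows(self):
        mat = np.array([
            [4.0, 6.0, 0.0, 0.0, 0.0, 0.0],  # only type A
            [2.0, 2.0, 1.0, 1.0, 1.0, 1.0],  # means (2, 1, 1)
        ])
        spec = self._spec(mat, ["A", "A", "B", "B", "C", "C"])
        np.testing.assert_allclose(spec.loc["g0"], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(spec.loc["g1"], [0.5, 0.25, 0.25])

    def test_equal_means_give_uniform_row(self):
        mat = np.ones((1, 8))
        spec = self._spec(mat, list("ABCD") * 2)
        np.testing.assert_allclose(spec.iloc[0], 0.25)

    def test_rows_sum_to_one_and_zero_genes_dropped(self, sim_bundle):
        norm = sp.normalize(sim_bundle["counts"])
        spec = sp.specificity_matrix(norm, sim_bundle["ann"])
        np.testing.assert_allclose(spec.sum(axis=1), 1.0, atol=1e-9)
        assert (spec.to_numpy() >= 0).all()

    def test_cell_permutation_invariance(self, sim_bundle):
        norm = sp.normalize(sim_bundle["counts"].iloc[:50])
        ann = sim_bundle["ann"]
        spec = sp.specificity_matrix(norm, ann)
        rng = np.random.default_rng(0)
        perm = rng.permutation(norm.columns)
        spec2 = sp.specificity_matrix(norm[perm], ann)
        pd.testing.assert_frame_equal(spec, spec2[spec.columns])

    def test_single_cell_type_is_error(self):
        with pytest.raises(ValueError):
            self._spec(np.ones((2, 3)), ["A", "A", "A"])


class TestTopFractionSet:
    @pytest.fixture()
    def spec100(self):
        rng = np.random.default_rng(2)
        vals = rng.random((100, 3))
        vals /= vals.sum(1, keepdims=True)
        return pd.DataFrame(vals, index=[f"g{i:03d}" for i in range(100)],
                            columns=["A", "B", "C"])

    def test_decile_of_100_is_10_top_ranked(self, spec100):
        out = sp.top_fraction_set(spec100, "A", 0.1)
        assert len(out) == 10
        cutoff = min(spec100.loc[list(out), "A"])
        assert (spec100.drop(index=list(out))["A"] <= cutoff).all()

    def test_top_n_larger_than_universe_errors_by_default(self, spec100):
        with pytest.raises(ValueError):
            sp.top_fraction_set(spec100, "A", 2000)
        assert len(sp.top_fraction_set(spec100, "A", 2000, allow_short=True)) == 100

    def test_ties_broken_by_gene_id(self):
        spec = pd.DataFrame({"A": [0.5, 0.5, 0.5, 0.5], "B": [0.5] * 4},
                            index=["g3", "g1", "g2", "g0"])
        out1 = sp.top_fraction_set(spec, "A", 0.5)
        out2 = sp.top_fraction_set(spec, "A", 0.5)
        assert out1 == out2 == {"g0", "g1"}

    def test_biotype_filter(self, spec100):
        genes = pd.DataFrame({
            "gene_id": spec100.index,
            "chrom": "1", "start": 1, "end": 2, "strand": "+",
            "biotype": ["protein_coding" if i % 2 else "noncoding"
                        for i in range(100)],
        })
        pc = sp.top_fraction_set(spec100, "A", 0.1, "protein_coding", genes)
        nc = sp.top_fraction_set(spec100, "A", 0.1, "noncoding", genes)
        assert len(pc) == len(nc) == 5
        assert not pc & nc

    def test_bad_fraction_is_error(self, spec100):
        with pytest.raises(ValueError):
            sp.top_fraction_set(spec100, "A", 1.5)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"1", "2", "3"}, {"2", "3", "4"}, 0.5),
            (set(), set(), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert sp.jaccard(a, b) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_bounds_and_symmetry(self, a, b):
        j = sp.jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == sp.jaccard(b, a)
        if a == b and a:
            assert j == 1.0
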