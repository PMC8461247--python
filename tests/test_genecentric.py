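import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tensoromics.genecentric import (
    assemble_tensor,
    filter_genes,
    impute_row_mean,
    log2_quantile_normalize,
    methylation_to_gene,
    minmax_scale_slice,
    mirna_to_gene,
    promoter_window,
    quantile_normalize,
)
from tensoromics.io import GeneAnnotation, OmicsMatrix


def _mat(values, name="GE", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(name, genes, samples, values)


class TestQuantileNormalize:
    def test_worked_2x2_example(self):
        out, _ = quantile_normalize(np.array([[1.0, 4.0], [3.0, 2.0]]))
        np.testing.assert_allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([0.3, 2.0, 1.1])
        x = np.column_stack([col, col, col])
        out, _ = quantile_normalize(x)
        np.testing.assert_allclose(out, x)

    def test_all_zero_matrix_stays_zero(self):
        m, _ = log2_quantile_normalize(_mat(np.zeros((4, 3))))
        np.testing.assert_allclose(m.values, 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_quantile_normalize(_mat([[-1.0, 2.0]]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 12), st.integers(2, 6))
    def test_columns_share_one_multiset(self, seed, n, m):
        """Post-condition: all sorted columns identical to 1e-12."""
        x = np.random.default_rng(seed).uniform(0, 50, (n, m))
        out, _ = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(m):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_tied_values_get_mean_of_tied_reference(self):
        # column 2 is constant: its three ranks tie, so every entry gets
        # the mean of all three reference values
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        out, ref = quantile_normalize(x)
        np.testing.assert_allclose(out[:, 1], ref.mean())

    def test_external_reference_maps_new_columns(self):
        train = np.random.default_rng(0).uniform(0, 10, (20, 5))
        _, ref = quantile_normalize(train)
        test = np.random.default_rng(1).uniform(0, 10, (20, 2))
        out, _ = quantile_normalize(test, reference=ref)
        np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(ref))


class TestMethylationToGene:
    ANN = {
        "gPlus": GeneAnnotation("gPlus", "chr1", "+", 10_000, "protein_coding"),
        "gMinus": GeneAnnotation("gMinus", "chr1", "-", 50_000, "protein_coding"),
        "gNoProbe": GeneAnnotation("gNoProbe", "chr2", "+", 10_000, "protein_coding"),
    }

    def _manifest(self, rows):
        return pd.DataFrame(
            rows, columns=["probe_id", "chrom", "pos"]
        ).set_index("probe_id")

    def test_mean_of_window_probes(self):
        probes = _mat([[0.2, 0.6], [0.4, 0.8]], name="meth",
                      genes=["cg1", "cg2"])
        manifest = self._manifest([("cg1", "chr1", 9_500), ("cg2", "chr1", 9_900)])
        out = methylation_to_gene(probes, manifest, self.ANN)
        assert out.gene_ids == ["gPlus"]
        np.testing.assert_allclose(out.values[0], [0.3, 0.7])

    def test_windows_are_strand_aware(self):
        # one probe downstream of the '-' TSS (inside its window), one
        # upstream of it (outside)
        probes = _mat([[0.9], [0.1]], name="meth", genes=["cgIn", "cgOut"])
        manifest = self._manifest([("cgIn", "chr1", 51_000), ("cgOut", "chr1", 49_000)])
        out = methylation_to_gene(probes, manifest, self.ANN)
        assert out.gene_ids == ["gMinus"]
        np.testing.assert_allclose(out.values[0], [0.9])
        lo, hi = promoter_window(self.ANN["gPlus"], 2000)
        assert (lo, hi) == (10_000 - 2000 - 1, 10_000)

    def test_gene_without_window_probe_absent(self):
        probes = _mat([[0.5]], name="meth", genes=["cg1"])
        manifest = self._manifest([("cg1", "chr1", 9_500)])
        out = methylation_to_gene(probes, manifest, self.ANN)
        assert "gNoProbe" not in out.gene_ids

    def test_missing_sample_uses_remaining_probes(self):
        probes = _mat([[0.2, np.nan], [0.4, 0.8]], name="meth",
                      genes=["cg1", "cg2"])
        manifest = self._manifest([("cg1", "chr1", 9_500), ("cg2", "chr1", 9_900)])
        out = methylation_to_gene(probes, manifest, self.ANN)
        np.testing.assert_allclose(out.values[0], [0.3, 0.8])

    def test_all_missing_probes_dropped_first(self):
        probes = _mat([[np.nan, np.nan], [0.4, 0.8]], name="meth",
                      genes=["cgDead", "cg2"])
        manifest = self._manifest([("cgDead", "chr1", 9_500), ("cg2", "chr1", 9_900)])
        out = methylation_to_gene(probes, manifest, self.ANN)
        np.testing.assert_allclose(out.values[0], [0.4, 0.8])

    def test_beta_range_enforced(self):
        probes = _mat([[1.5]], name="meth", genes=["cg1"])
        manifest = self._manifest([("cg1", "chr1", 9_500)])
        with pytest.raises(ValueError, match="beta"):
            methylation_to_gene(probes, manifest, self.ANN)


class TestMirnaToGene:
    def test_geometric_mean_matches_log_oracle(self):
        # bundle (2, 8): with the log1p pseudocount the value is
        # exp(mean(ln(3), ln(9))) - 1
        m = _mat([[2.0], [8.0]], name="mirna", genes=["m1", "m2"])
        out = mirna_to_gene(m, {"m1": {"gA"}, "m2": {"gA"}})
        expected = np.exp(np.mean(np.log([3.0, 9.0]))) - 1.0
        np.testing.assert_allclose(out.values[0, 0], expected)

    def test_single_mirna_bundle_is_identity(self):
        m = _mat([[5.0, 7.0]], name="mirna", genes=["m1"])
        out = mirna_to_gene(m, {"m1": {"gA"}})
        np.testing.assert_allclose(out.values[0], [5.0, 7.0])

    def test_untargeted_gene_gets_zero(self):
        m = _mat([[5.0]], name="mirna", genes=["m1"])
        out = mirna_to_gene(m, {"m1": {"gA"}}, gene_ids=["gA", "gB"])
        np.testing.assert_allclose(out.values[1], 0.0)

    def test_all_zero_mirnas_excluded(self):
        m = _mat([[0.0, 0.0], [4.0, 6.0]], name="mirna", genes=["mDead", "m2"])
        out = mirna_to_gene(m, {"mDead": {"gA"}, "m2": {"gA"}})
        np.testing.assert_allclose(out.values[0], [4.0, 6.0])

    def test_arithmetic_mode(self):
        m = _mat([[2.0], [8.0]], name="mirna", genes=["m1", "m2"])
        out = mirna_to_gene(m, {"m1": {"gA"}, "m2": {"gA"}}, mode="arithmetic")
        np.testing.assert_allclose(out.values[0, 0], 5.0)

    def test_empty_target_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mirna_to_gene(_mat([[1.0]], name="mirna", genes=["m1"]), {})


class TestFilterGenes:
    ANN = {
        "gA": GeneAnnotation("gA", "chr1", "+", 1000, "protein_coding"),
        "gB": GeneAnnotation("gB", "chr1", "+", 2000, "lincRNA"),
        "gC": GeneAnnotation("gC", "chr1", "+", 3000, "protein_coding"),
    }

    def test_missingness_biotype_and_presence(self):
        n = 100
        expr = _mat(np.ones((3, n)), genes=["gA", "gB", "gC"],
                    samples=[f"s{j}" for j in range(n)])
        meth_values = np.ones((3, n))
        meth_values[2, :81] = np.nan  # gC missing in 81% of samples
        meth = _mat(meth_values, name="ME", genes=["gA", "gB", "gC"],
                    samples=expr.sample_ids)
        kept = filter_genes([expr, meth], self.ANN)
        assert kept == ["gA"]  # gB wrong biotype, gC too missing

    def test_exactly_80_percent_missing_is_kept(self):
        n = 100
        expr = _mat(np.ones((1, n)), genes=["gA"],
                    samples=[f"s{j}" for j in range(n)])
        v = np.ones((1, n))
        v[0, :80] = np.nan
        meth = _mat(v, name="ME", genes=["gA"], samples=expr.sample_ids)
        assert filter_genes([expr, meth], self.ANN) == ["gA"]

    def test_gene_must_be_in_every_matrix(self):
        expr = _mat(np.ones((2, 2)), genes=["gA", "gC"])
        meth = _mat(np.ones((1, 2)), name="ME", genes=["gA"])
        assert filter_genes([expr, meth], self.ANN) == ["gA"]


class TestScalingAndAssembly:
    def test_minmax_midpoint(self):
        m, bounds = minmax_scale_slice(_mat([[2.0, 6.0], [10.0, 4.0]]))
        assert bounds == (2.0, 10.0)
        np.testing.assert_allclose(m.values[0, 1], 0.5)
        assert m.values.min() == 0.0 and m.values.max() == 1.0

    def test_constant_slice_maps_to_zero(self):
        m, _ = minmax_scale_slice(_mat(np.full((2, 2), 7.0)))
        np.testing.assert_allclose(m.values, 0.0)

    def test_assemble_shape_and_slice_identity(self, rng):
        mats = [
            _mat(rng.uniform(0, 1, (10, 4)), name=n) for n in ("GE", "ME", "MI")
        ]
        tensor = assemble_tensor(mats, scale=False)
        assert tensor.shape == (10, 4, 3)
        np.testing.assert_array_equal(tensor.slice("ME").values, mats[1].values)

    def test_missing_cell_imputed_to_row_mean(self):
        v = np.array([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]])
        out = impute_row_mean(_mat(v))
        np.testing.assert_allclose(out.values[0, 1], 2.0)
        tensor = assemble_tensor([_mat(v, name="GE")])
        assert not np.isnan(tensor.values).any()

    def test_axis_mismatch_rejected(self):
        a = _mat(np.ones((2, 2)), name="GE")
        b = _mat(np.ones((3, 2)), name="ME")
        with pytest.raises(ValueError, match="mismatch|shape|axis"):
            assemble_tensor([a, b])

    def test_tensor_entries_in_unit_interval(self, rng):
        mats = [_mat(rng.uniform(-3, 50, (8, 5)), name=n) for n in ("GE", "ME")]
        tensor = assemble_tensor(mats, scale=True)
        assert tensor.values.min() >= 0.0 and tensor.values.max() <= 1.0

    def test_tensor_disk_roundtrip(self, tmp_path, rng):
        mats = [_mat(rng.uniform(0, 1, (6, 3)), name=n) for n in ("GE", "ME", "MI")]
        tensor = assemble_tensor(mats, scale=True)
        tensor.write(tmp_path / "t")
        back = type(tensor).read(tmp_path / "t")
        np.testing.assert_allclose(back.values, tensor.values, atol=1e-9)
        assert back.omics_names == tensor.omics_names
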