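"""Imaging and genomics preprocessing operations."""

import numpy as np
import pytest
from skimage.draw import disk

from quarg import preprocess, synthetic
from quarg.preprocess import GenomicMatrix, ImagePatch


class TestBiasField:
    def test_constant_image_unchanged(self):
        patch = ImagePatch(np.full((20, 20), 3.0))
        out = preprocess.correct_bias_field(patch)
        assert np.allclose(out.pixels, 3.0, rtol=1e-9)

    def test_mean_brightness_preserved(self):
        biased, _ = synthetic.generate_image_patch(1, size=32, bias=True, seed=4)
        out = preprocess.correct_bias_field(ImagePatch(biased))
        assert abs(out.pixels.mean() - biased.mean()) / biased.mean() < 0.01

    def test_planted_field_reduced_5x(self):
        """Residual low-frequency variation after correction drops >= 5x."""
        biased, _ = synthetic.generate_image_patch(1, size=32, bias=True, seed=4)
        before = preprocess.fit_bias_field(ImagePatch(biased), order=2).std()
        corrected = preprocess.correct_bias_field(ImagePatch(biased), order=2)
        after = preprocess.fit_bias_field(corrected, order=2).std()
        assert before / max(after, 1e-12) >= 5.0

    def test_nonfinite_pixels_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ImagePatch(np.array([[1.0, np.inf], [0.5, 1.0]]))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            preprocess.fit_bias_field(ImagePatch(np.ones((8, 8))), order=5)


class TestExtractRoi:
    def test_full_mask_margin_zero_is_identity(self):
        patch = ImagePatch(np.arange(36.0).reshape(6, 6))
        out = preprocess.extract_roi(patch, np.ones((6, 6)), margin=0)
        assert np.array_equal(out.pixels, patch.pixels)

    def test_single_pixel_mask_with_margin(self):
        patch = ImagePatch(np.zeros((12, 12)))
        mask = np.zeros((12, 12))
        mask[5, 5] = 1
        out = preprocess.extract_roi(patch, mask, margin=2)
        assert out.pixels.shape == (5, 5)

    def test_edge_mask_clips_to_bounds(self):
        patch = ImagePatch(np.zeros((10, 10)))
        mask = np.zeros((10, 10))
        mask[0, 9] = 1
        out = preprocess.extract_roi(patch, mask, margin=3)
        assert out.pixels.shape == (4, 4)  # clipped at the top and right edges

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            preprocess.extract_roi(ImagePatch(np.zeros((5, 5))), np.zeros((5, 5)), 1)


class TestHarmonize:
    def test_identity_when_already_at_target(self):
        patch = ImagePatch(np.random.default_rng(0).normal(size=(9, 9)), 1.0)
        out = preprocess.harmonize([patch], target_spacing=1.0)[0]
        # resampling skipped; only the z-score applies
        ref = (patch.pixels - patch.pixels.mean()) / patch.pixels.std()
        assert np.allclose(out.pixels, ref, atol=1e-9)

    def test_outputs_are_zero_mean_unit_sd(self, rng):
        patches = [ImagePatch(rng.normal(size=(17, 17)), s) for s in (0.5, 1.0, 2.0)]
        for out in preprocess.harmonize(patches, target_spacing=1.0):
            assert abs(out.pixels.mean()) < 1e-9
            assert abs(out.pixels.std() - 1.0) < 1e-9
            assert out.pixel_spacing == 1.0

    def test_constant_patch_maps_to_zeros(self):
        out = preprocess.harmonize([ImagePatch(np.full((8, 8), 4.0), 2.0)], 1.0)[0]
        assert np.all(out.pixels == 0.0)


class TestRadiomics:
    def test_uniform_region_sd_zero_energy_one(self):
        patch = ImagePatch(np.full((15, 15), 2.0))
        mask = np.zeros((15, 15))
        mask[4:10, 4:10] = 1
        v = preprocess.radiomic_descriptors(patch, mask).as_dict()
        assert v["intensity_sd"] == 0.0
        assert v["glcm_energy"] == pytest.approx(1.0)

    def test_disc_circularity_near_one(self):
        mask = np.zeros((64, 64))
        rr, cc = disk((32, 32), 20)
        mask[rr, cc] = 1
        patch = ImagePatch(np.random.default_rng(1).normal(size=(64, 64)))
        v = preprocess.radiomic_descriptors(patch, mask).as_dict()
        assert 0.85 < v["circularity"] <= 1.1

    def test_intensity_scale_equivariance(self):
        rng = np.random.default_rng(2)
        pix = rng.uniform(1, 3, size=(20, 20))
        mask = np.zeros((20, 20))
        mask[5:15, 5:15] = 1
        v1 = preprocess.radiomic_descriptors(ImagePatch(pix), mask).as_dict()
        v2 = preprocess.radiomic_descriptors(ImagePatch(2 * pix), mask).as_dict()
        assert v2["intensity_mean"] == pytest.approx(2 * v1["intensity_mean"])
        assert v2["intensity_skewness"] == pytest.approx(v1["intensity_skewness"], abs=1e-9)

    def test_area_scales_with_spacing(self):
        mask = np.ones((10, 10))
        patch = ImagePatch(np.ones((10, 10)), pixel_spacing=0.5)
        v = preprocess.radiomic_descriptors(patch, mask).as_dict()
        assert v["area"] == pytest.approx(100 * 0.25)


class TestNormalizeExpression:
    def test_tpm_worked_example(self):
        """Two genes of 1 kb and 2 kb with counts 10 and 20 split TPM evenly."""
        m = GenomicMatrix(np.array([[10.0], [20.0]]), np.array([1.0, 2.0]))
        out = preprocess.normalize_expression(m, "TPM")
        assert np.allclose(2**out.values - 1, [[500000.0], [500000.0]])
        assert out.values[0, 0] == pytest.approx(18.93, abs=0.01)
        assert out.stage == "normalized"

    def test_zero_count_maps_to_zero(self):
        m = GenomicMatrix(np.array([[0.0], [5.0]]), np.array([1.0, 1.0]))
        out = preprocess.normalize_expression(m, "TPM")
        assert out.values[0, 0] == 0.0

    def test_tpm_columns_sum_to_1e6(self):
        counts, lengths = synthetic.generate_counts(100, 6, seed=1)
        m = GenomicMatrix(counts.astype(float), lengths)
        out = preprocess.normalize_expression(m, "TPM")
        sums = (2**out.values - 1).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_fpkm_definition(self):
        m = GenomicMatrix(np.array([[10.0], [20.0]]), np.array([1.0, 2.0]))
        out = preprocess.normalize_expression(m, "FPKM")
        lib = 30.0
        expected = np.log2(1 + np.array([[10e9 / (1000 * lib)], [20e9 / (2000 * lib)]]))
        assert np.allclose(out.values, expected)

    def test_zero_library_rejected_naming_sample(self):
        m = GenomicMatrix(np.array([[0.0, 1.0], [0.0, 2.0]]), np.array([1.0, 1.0]),
                          sample_ids=["s1", "s2"])
        with pytest.raises(ValueError, match="s1"):
            preprocess.normalize_expression(m)

    def test_stage_guard(self):
        m = GenomicMatrix(np.ones((2, 2)), np.ones(2), stage="normalized")
        with pytest.raises(ValueError, match="stage"):
            preprocess.normalize_expression(m)


class TestImputeKnn:
    def test_no_missing_is_identity(self):
        m = GenomicMatrix(np.arange(6.0).reshape(2, 3), np.ones(2), stage="normalized")
        out = preprocess.impute_knn(m, k=2)
        assert np.array_equal(out.values, m.values)
        assert out.stage == "imputed"

    def test_forced_nearest_neighbour(self):
        """Sample C matches A exactly on observed genes and is far from B."""
        vals = np.array(
            [
                [1.0, 9.0, 1.0],
                [2.0, 8.0, 2.0],
                [5.0, 7.0, np.nan],
            ]
        )
        m = GenomicMatrix(vals, np.ones(3), stage="normalized")
        out = preprocess.impute_knn(m, k=1)
        assert out.values[2, 2] == 5.0  # copied from sample A

    def test_k_equals_all_gives_observed_mean(self):
        """4-sample fixture: k = n-1 fills with the gene's observed mean."""
        vals = np.array(
            [
                [1.0, 2.0, 3.0, np.nan],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        m = GenomicMatrix(vals, np.ones(2), stage="normalized")
        out = preprocess.impute_knn(m, k=3)
        assert out.values[0, 3] == pytest.approx(2.0)

    def test_fully_missing_gene_rejected_by_name(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0]])
        m = GenomicMatrix(vals, np.ones(2), stage="normalized", gene_ids=["gA", "gB"])
        with pytest.raises(ValueError, match="gA"):
            preprocess.impute_knn(m)


class TestFilterStandardize:
    def _matrix(self, values):
        return GenomicMatrix(np.asarray(values, float), np.ones(len(values)), stage="imputed")

    def test_quantile_rule_removes_three_lowest_of_ten(self, rng):
        rows = [np.sqrt(v) * rng.standard_normal(50) for v in range(1, 11)]
        m = self._matrix(rows)
        out, stats = preprocess.filter_and_standardize(m, var_quantile=0.3)
        empirical_var = m.values.var(axis=1)
        dropped = sorted(set(range(10)) - set(stats.keep))
        assert len(dropped) == 3
        assert set(dropped) == set(np.argsort(empirical_var)[:3])

    def test_zero_quantile_only_drops_constant_genes(self, rng):
        m = self._matrix([rng.standard_normal(20), np.full(20, 5.0)])
        out, stats = preprocess.filter_and_standardize(m, var_quantile=0.0)
        assert list(stats.keep) == [0]

    def test_fit_split_is_zero_mean_unit_sd(self, rng):
        m = self._matrix(rng.standard_normal((6, 40)) * 3 + 1)
        out, _ = preprocess.filter_and_standardize(m, 0.0)
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.values.std(axis=1), 1.0, atol=1e-9)
        assert out.stage == "standardized"

    def test_training_stats_reused_on_held_out(self, rng):
        train = self._matrix(rng.standard_normal((5, 30)))
        test = self._matrix(rng.standard_normal((5, 10)) + 10)
        _, stats = preprocess.filter_and_standardize(train, 0.0)
        out, _ = preprocess.filter_and_standardize(test, 0.0, stats=stats)
        # held-out data transformed with the training mean: shift survives
        assert out.values.mean() > 5.0

    def test_all_filtered_rejected(self):
        m = self._matrix([np.full(10, 1.0), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="every gene"):
            preprocess.filter_and_standardize(m, 0.5)


class TestCsvRoundTrip:
    def test_matrix_and_lengths_round_trip(self, tmp_path, rng):
        m = GenomicMatrix(
            rng.integers(0, 50, size=(6, 4)).astype(float),
            rng.uniform(0.2, 20, 6),
            sample_ids=[f"s{j}" for j in range(4)],
            gene_ids=[f"g{i}" for i in range(6)],
        )
        m.to_csv(tmp_path / "expr.csv", tmp_path / "lengths.csv")
        back = preprocess.GenomicMatrix.from_csv(
            tmp_path / "expr.csv", tmp_path / "lengths.csv"
        )
        assert np.allclose(back.values, m.values)
        assert np.allclose(back.gene_lengths_kb, m.gene_lengths_kb)
        assert back.sample_ids == m.sample_ids and back.stage == "raw"
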