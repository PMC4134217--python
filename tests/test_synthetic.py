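"""Generator of artificial two-subject activation datasets."""

import numpy as np
import pytest

from gsvc.synthetic import (
    InvalidGeometryError,
    ROIData,
    SubjectPatternSpec,
    SyntheticConfig,
    derive_seed,
    generate_dataset,
    load_npz,
    overlap_to_offset,
    read_dataset,
    save_npz,
    smooth_gaussian,
    true_band_assignment,
    true_pattern,
    variability_grid,
    write_dataset,
)
from oracles import direct_gaussian_convolution


class TestOverlapToOffset:
    @pytest.mark.parametrize("overlap,expected", [
        (1.0, 20),   # zero shift keeps subject 2 at subject 1's offset of 20
        (0.67, 30),
        (0.33, 40),
        (0.0, 50),   # shift equal to the band height eliminates overlap
    ])
    def test_canonical_levels(self, overlap, expected):
        assert overlap_to_offset(overlap, middle_height=30, b_s1=20) == expected

    def test_realized_overlap_matches_request(self):
        """The fraction of middle-band rows shared by the two subjects equals
        the requested overlap exactly at the canonical levels."""
        h = 30
        for overlap in (1.0, 0.67, 0.33, 0.0):
            b2 = overlap_to_offset(overlap, h, 20)
            shared = max(0, min(20 + h, b2 + h) - max(20, b2))
            assert shared == round(overlap * h)

    def test_invalid_geometry_raises(self):
        with pytest.raises(InvalidGeometryError):
            overlap_to_offset(0.0, middle_height=30, b_s1=75)

    def test_out_of_range_fraction_raises(self):
        with pytest.raises(ValueError):
            overlap_to_offset(1.5, 30, 20)


class TestTruePattern:
    def test_band_levels_per_condition(self):
        spec = SubjectPatternSpec(middle_offset=20)
        for y, level in [(1, 1.0), (2, 2.0)]:
            img = true_pattern(spec, y)
            assert img.shape == (100, 20)
            assert np.all(img[:20] == 0.0)
            assert np.all(img[20:50] == level)
            assert np.all(img[50:] == 0.0)

    def test_eta_shifts_band_uniformly(self):
        spec = SubjectPatternSpec(middle_offset=20, eta={(1, 1): 0.3})
        img = true_pattern(spec, 1)
        assert np.all(img[20:50] == 1.3)
        assert np.all(img[:20] == 0.0)

    def test_unknown_condition_raises(self):
        with pytest.raises(ValueError):
            true_pattern(SubjectPatternSpec(middle_offset=20), 7)

    def test_band_outside_grid_raises(self):
        with pytest.raises(InvalidGeometryError):
            SubjectPatternSpec(middle_offset=80, middle_height=30)


class TestSmoothGaussian:
    def test_zero_fwhm_is_identity(self):
        img = np.random.default_rng(0).normal(size=(30, 10))
        assert np.array_equal(smooth_gaussian(img, 0.0), img)

    def test_constants_are_preserved(self):
        img = np.full((40, 15), 3.25)
        assert np.allclose(smooth_gaussian(img, 2.35), img)

    def test_impulse_matches_direct_convolution(self):
        """Smoothing a centred unit impulse agrees with an explicit 2-D
        convolution, and the implied sigma is FWHM / 2.355."""
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        fwhm = 2.35
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = smooth_gaussian(img, fwhm)
        ref = direct_gaussian_convolution(img, sigma)
        assert np.allclose(out, ref, atol=1e-6)
        assert out[10, 10] == out.max()

    def test_mean_preserved_for_interior_mass(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(100, 20))
        out = smooth_gaussian(img, 2.35)
        assert abs(out.mean() - img.mean()) < 0.01


class TestGenerateDataset:
    def test_shapes_and_balanced_labels(self):
        subjects = generate_dataset(SyntheticConfig(seed=0))
        assert len(subjects) == 2
        for roi in subjects:
            assert roi.coords.shape == (2000, 2)
            assert roi.activations.shape == (2000, 20)
            assert np.sum(roi.labels == 1) == 10
            assert np.sum(roi.labels == 2) == 10

    def test_no_noise_means_identical_trials_within_condition(self):
        subjects = generate_dataset(SyntheticConfig(sigma_pix=0.0, sigma_eta=0.0, seed=0))
        for roi in subjects:
            for y in (1, 2):
                cols = roi.activations[:, roi.labels == y]
                assert np.all(cols == cols[:, :1])

    def test_noiseless_between_condition_contrast_is_one(self):
        subjects = generate_dataset(SyntheticConfig(sigma_pix=0.0, sigma_eta=0.0, seed=0))
        roi = subjects[0]
        band = true_band_assignment(SyntheticConfig(sigma_pix=0.0), 0) == 1
        mid1 = roi.activations[band][:, roi.labels == 1].mean()
        mid2 = roi.activations[band][:, roi.labels == 2].mean()
        assert mid2 - mid1 == 1.0

    def test_same_seed_is_bit_identical(self):
        a = generate_dataset(SyntheticConfig(seed=123))
        b = generate_dataset(SyntheticConfig(seed=123))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.activations, rb.activations)
            assert np.array_equal(ra.coords, rb.coords)
            assert np.array_equal(ra.labels, rb.labels)

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(seed=1))
        b = generate_dataset(SyntheticConfig(seed=2))
        assert not np.array_equal(a[0].activations, b[0].activations)

    def test_eta_fixed_across_trials_within_dataset(self):
        """With sigma_eta > 0 but no pixel noise, trials of one condition are
        still identical: the band perturbation is drawn once per dataset."""
        subjects = generate_dataset(SyntheticConfig(sigma_eta=0.3, sigma_pix=0.0, seed=4))
        for roi in subjects:
            cols = roi.activations[:, roi.labels == 1]
            assert np.all(cols == cols[:, :1])


class TestVariabilityGrid:
    def test_full_grid_counts(self):
        cases = list(variability_grid([1.0, 0.67, 0.33, 0.0], [0.0, 0.1, 0.2, 0.3],
                                      n_datasets=2, seed=0, sigma_pix=0.0))
        assert len(cases) == 32

    def test_single_cell(self):
        cases = list(variability_grid([1.0], [0.0], 1, seed=0))
        assert len(cases) == 1

    def test_derived_seeds_all_distinct(self):
        seeds = [case["seed"]
                 for case, _ in variability_grid([1.0, 0.0], [0.0, 0.2], 20, seed=3,
                                                 sigma_pix=0.0)]
        assert len(set(seeds)) == len(seeds)
        assert all(0 <= s < 2 ** 31 for s in seeds)

    def test_empty_lists_raise(self):
        with pytest.raises(ValueError):
            next(variability_grid([], [0.0], 1))


class TestROIDataValidation:
    def test_mismatched_labels_raise(self):
        with pytest.raises(ValueError):
            ROIData("s", np.array([[0.0, 0], [1, 0]]), np.ones((2, 3)), np.array([1, 2]))

    def test_duplicate_coords_raise(self):
        with pytest.raises(ValueError):
            ROIData("s", np.zeros((2, 2)), np.ones((2, 1)), np.array([1]))


class TestDatasetIO:
    def test_csv_round_trip(self, tmp_path):
        subjects = generate_dataset(SyntheticConfig(seed=9))
        write_dataset(tmp_path / "ds", subjects)
        loaded = read_dataset(tmp_path / "ds")
        assert [r.subject_id for r in loaded] == [r.subject_id for r in subjects]
        for a, b in zip(subjects, loaded):
            assert np.allclose(a.activations, b.activations)
            assert np.array_equal(a.labels, b.labels)
            assert np.allclose(a.coords, b.coords)

    def test_npz_round_trip(self, tmp_path):
        subjects = generate_dataset(SyntheticConfig(seed=9))
        save_npz(tmp_path / "ds.npz", subjects)
        loaded = load_npz(tmp_path / "ds.npz")
        for a, b in zip(subjects, loaded):
            assert np.array_equal(a.activations, b.activations)


def test_derive_seed_is_stable_and_bounded():
    assert derive_seed(7, 1, 2) == derive_seed(7, 1, 2)
    assert derive_seed(7, 1, 2) != derive_seed(7, 2, 1)
    assert 0 <= derive_seed(7, 1, 2) < 2 ** 31
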