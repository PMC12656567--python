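"""Synthetic scene generator: determinism, simplex truth, forward model."""

import numpy as np
import pytest

from grassunmix.errors import DataError
from grassunmix.linear_unmixing import unmix_cube
from grassunmix.synthetic_scene import (
    ClassSpec,
    DEFAULT_CLASSES,
    SceneTruth,
    generate_endmember_spectra,
    generate_fraction_field,
    make_scene_truth,
    neon_wavelength_grid,
    render_cube,
    sample_reference_points,
)


def spectral_angle_oracle(s1, s2):
    """Direct arccos-of-normalised-dot-product formula."""
    return np.arccos(
        np.clip(s1 @ s2 / (np.linalg.norm(s1) * np.linalg.norm(s2)), -1, 1)
    )


class TestEndmemberSpectra:
    def test_neon_band_geometry(self):
        lib = generate_endmember_spectra(426, DEFAULT_CLASSES, seed=0)
        assert lib.n_bands == 426
        assert lib.wavelengths_nm[0] == 380.0
        assert np.all(np.diff(lib.wavelengths_nm) == 5.0)

    def test_same_seed_bitwise_identical(self):
        a = generate_endmember_spectra(200, DEFAULT_CLASSES, seed=42)
        b = generate_endmember_spectra(200, DEFAULT_CLASSES, seed=42)
        assert np.array_equal(a.spectra, b.spectra)

    def test_pairwise_separability_by_angle_oracle(self):
        lib = generate_endmember_spectra(
            426, DEFAULT_CLASSES, seed=3, min_separation_rad=0.02
        )
        for i in range(lib.n_classes):
            for j in range(i + 1, lib.n_classes):
                assert (
                    spectral_angle_oracle(lib.spectra[i], lib.spectra[j]) >= 0.02
                )

    def test_vegetation_red_edge_and_soil_monotone_trend(self):
        lib = generate_endmember_spectra(426, DEFAULT_CLASSES, seed=5)
        wl = lib.wavelengths_nm
        red = (wl >= 650) & (wl <= 690)
        nir = (wl >= 780) & (wl <= 900)
        for name in ("herbaceous", "mixed_forbs"):
            s = lib.spectra[lib.class_names.index(name)]
            assert s[nir].mean() > 2 * s[red].mean()
        soil = lib.spectra[lib.class_names.index("bare_soil")]
        # broad monotone trend, no red/NIR jump
        assert soil[nir].mean() < 2 * soil[red].mean()
        coarse = soil[:: soil.size // 10]
        assert np.all(np.diff(coarse) > -0.05)

    def test_spectra_non_negative(self):
        lib = generate_endmember_spectra(300, DEFAULT_CLASSES, seed=8)
        assert np.all(lib.spectra >= 0)

    @pytest.mark.parametrize(
        "n_bands,specs",
        [
            (1, DEFAULT_CLASSES),
            (0, DEFAULT_CLASSES),
            (100, DEFAULT_CLASSES[:1]),
        ],
    )
    def test_rejects_bad_inputs(self, n_bands, specs):
        with pytest.raises(DataError):
            generate_endmember_spectra(n_bands, specs, seed=0)


class TestFractionField:
    def test_single_class_is_exactly_one(self):
        stack = generate_fraction_field(5, 7, [2.0], seed=1)
        assert np.array_equal(stack.fractions, np.ones((1, 5, 7)))

    def test_per_pixel_sums_equal_one(self):
        stack = generate_fraction_field(
            30, 30, [0.2, 0.5, 1.5], smoothness_px=1.2, seed=4
        )
        sums = stack.fractions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert stack.fractions.min() >= 0

    def test_symmetric_concentration_means_one_third(self):
        # Dirichlet(1,1,1) has mean 1/3, var = 1/3*2/3/4 = 1/18 per component
        stack = generate_fraction_field(200, 200, [1, 1, 1], 0.0, seed=2)
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / (200 * 200))
        for layer in stack.fractions:
            assert abs(layer.mean() - 1 / 3) < 3 * se

    def test_same_seed_bitwise_identical(self):
        a = generate_fraction_field(10, 10, [0.3, 0.7], 0.5, seed=9)
        b = generate_fraction_field(10, 10, [0.3, 0.7], 0.5, seed=9)
        assert np.array_equal(a.fractions, b.fractions)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rows=0, cols=5, concentration=[1, 1]),
            dict(rows=5, cols=5, concentration=[1, -1]),
            dict(rows=5, cols=5, concentration=[1, 1], smoothness_px=-1),
        ],
    )
    def test_rejects_bad_inputs(self, kwargs):
        with pytest.raises(DataError):
            generate_fraction_field(seed=0, **kwargs)


class TestRenderCube:
    def test_pure_pixel_equals_library_row(self, small_truth):
        lib = small_truth.library
        frac = np.zeros((3, 1, 1))
        frac[1, 0, 0] = 1.0
        truth = SceneTruth(
            fractions=type(small_truth.fractions)(
                fractions=frac, class_names=lib.class_names
            ),
            library=lib,
            noise_sd=0.0,
        )
        cube = render_cube(truth)
        assert np.allclose(cube.reflectance[0, 0], lib.spectra[1], atol=1e-12)

    def test_noiseless_cube_is_invertible(self, small_truth, small_cube):
        stack = unmix_cube(small_cube, small_truth.library, "fcls")
        err = np.abs(stack.fractions - small_truth.fractions.fractions)
        assert err.max() < 1e-6

    def test_reconstruction_rmse_matches_noise_level(self):
        truth = make_scene_truth(
            rows=40, cols=40, n_bands=200, noise_sd=0.01,
            corrupted_band_ranges=(), n_nodata=0, n_negative=0, seed=13,
        )
        cube = render_cube(truth)
        recon = np.einsum(
            "krc,kb->rcb", truth.fractions.fractions, truth.library.spectra
        )
        rmse = np.sqrt(np.mean((cube.reflectance - recon) ** 2))
        assert abs(rmse - 0.01) < 0.2 * 0.01

    def test_class_count_mismatch_rejected(self, small_truth):
        lib2 = generate_endmember_spectra(
            120, DEFAULT_CLASSES[:2], seed=1
        )
        with pytest.raises(DataError):
            SceneTruth(fractions=small_truth.fractions, library=lib2)

    def test_same_seed_bitwise_identical(self, small_truth):
        assert np.array_equal(
            render_cube(small_truth).reflectance,
            render_cube(small_truth).reflectance,
        )

    def test_defect_injection(self, noisy_truth, noisy_cube):
        for r, c in noisy_truth.nodata_pixels:
            assert np.all(noisy_cube.reflectance[r, c] == -0.9999)
        for r, c in noisy_truth.negative_pixels:
            assert noisy_cube.reflectance[r, c].min() < 0


class TestReferencePoints:
    def test_points_satisfy_purity_by_lookup(self, noisy_truth):
        pts = sample_reference_points(noisy_truth, 30, purity=0.75, seed=5)
        stack = noisy_truth.fractions
        rows, cols = stack.rowcol_of_xy(pts.x, pts.y)
        for r, c, lab in zip(rows, cols, pts.labels):
            ci = stack.class_names.index(lab)
            assert stack.fractions[ci, r, c] >= 0.75

    def test_counts_and_no_duplicate_locations(self, noisy_truth):
        pts = sample_reference_points(noisy_truth, 25, purity=0.75, seed=6)
        assert len(pts) == 75
        assert len({(x, y) for x, y in zip(pts.x, pts.y)}) == 75

    def test_insufficient_pixels_error_names_class(self, small_truth):
        with pytest.raises(DataError, match="herbaceous"):
            sample_reference_points(small_truth, 10**6, purity=1.0, seed=0)

    def test_one_hot_truth_yields_one_hot_points(self):
        frac = np.zeros((2, 6, 6))
        frac[0, :3] = 1.0
        frac[1, 3:] = 1.0
        lib = generate_endmember_spectra(
            120, DEFAULT_CLASSES[:2], seed=2
        )
        from grassunmix.types import FractionStack

        truth = SceneTruth(
            fractions=FractionStack(
                fractions=frac, class_names=lib.class_names
            ),
            library=lib,
        )
        pts = sample_reference_points(truth, 5, purity=1.0, seed=1)
        stack = truth.fractions
        rows, cols = stack.rowcol_of_xy(pts.x, pts.y)
        for r, c, lab in zip(rows, cols, pts.labels):
            ci = stack.class_names.index(lab)
            assert stack.fractions[ci, r, c] == 1.0
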