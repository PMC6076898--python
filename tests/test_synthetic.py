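"""Synthetic study generator: design counts, determinism, SNV structure."""

import numpy as np
import pytest

from nirdd.spectra import snv_transform
from nirdd.synthetic import (
    BrandRecipe,
    default_brand_library,
    default_grid,
    simulate_spectra,
    simulate_study,
)


class TestBrandLibrary:
    def test_three_recipes_shared_centers_distinct_amplitudes(self):
        lib = default_brand_library()
        assert len(lib) == 3
        assert [r.name for r in lib] == ["A", "B", "C"]
        for r in lib[1:]:
            np.testing.assert_array_equal(r.band_centers, lib[0].band_centers)
        amps = [tuple(r.band_amplitudes) for r in lib]
        assert len(set(amps)) == 3

    def test_zero_separation_makes_brands_identical(self):
        lib = default_brand_library(separation=0.0)
        for r in lib[1:]:
            np.testing.assert_array_equal(r.band_amplitudes, lib[0].band_amplitudes)

    def test_recipe_validation(self):
        with pytest.raises(ValueError, match="width"):
            BrandRecipe("X", [5000.0], [1.0], [0.0])
        with pytest.raises(ValueError, match="equal length"):
            BrandRecipe("X", [5000.0], [1.0, 2.0], [10.0])
        with pytest.raises(ValueError, match="scatter"):
            BrandRecipe("X", [5000.0], [1.0], [10.0], scatter_factor_range=(-1, 1))


class TestSimulateSpectra:
    def test_deterministic_for_fixed_seed(self):
        recipe = default_brand_library()[0]
        a = simulate_spectra(recipe, 5, seed=42)
        b = simulate_spectra(recipe, 5, seed=42)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_noiseless_limit_equals_band_sum(self):
        from dataclasses import replace

        recipe = replace(
            default_brand_library()[0],
            noise_sd=0.0,
            amplitude_jitter_rel=0.0,
            scatter_factor_range=(1.0, 1.0),
            baseline_offset_range=(0.0, 0.0),
            baseline_slope_range=(0.0, 0.0),
        )
        grid = default_grid()
        out = simulate_spectra(recipe, 3, grid, seed=0)
        expected = recipe.band_sum(grid)
        np.testing.assert_allclose(
            out.absorbance, np.tile(expected, (3, 1)), atol=1e-12
        )

    def test_same_brand_spectra_correlate_after_snv(self):
        recipe = default_brand_library()[0]
        out = snv_transform(simulate_spectra(recipe, 10, seed=3))
        X = out.absorbance
        cc = np.corrcoef(X)
        off = cc[np.triu_indices(10, 1)]
        assert off.min() > 0.99

    def test_scatter_and_offset_removed_by_snv(self):
        """Two draws differing only in scatter/offset agree after SNV."""
        from dataclasses import replace

        base = replace(
            default_brand_library()[0],
            noise_sd=0.0,
            amplitude_jitter_rel=0.0,
            baseline_slope_range=(0.0, 0.0),
            scatter_factor_range=(1.0, 1.0),
            baseline_offset_range=(0.0, 0.0),
        )
        distorted = replace(
            base,
            scatter_factor_range=(1.7, 1.7),
            baseline_offset_range=(0.3, 0.3),
        )
        a = snv_transform(simulate_spectra(base, 1, seed=0)).absorbance
        b = snv_transform(simulate_spectra(distorted, 1, seed=0)).absorbance
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_default_slope_leaves_small_snv_residual(self):
        """The mild baseline slope is not exactly removed by SNV but stays
        well below the between-brand signal."""
        from dataclasses import replace

        base = replace(
            default_brand_library()[0],
            noise_sd=0.0,
            amplitude_jitter_rel=0.0,
            scatter_factor_range=(1.0, 1.0),
            baseline_offset_range=(0.0, 0.0),
            baseline_slope_range=(0.0, 0.0),
        )
        sloped = replace(base, baseline_slope_range=(0.01, 0.01))
        a = snv_transform(simulate_spectra(base, 1, seed=0)).absorbance
        b = snv_transform(simulate_spectra(sloped, 1, seed=0)).absorbance
        assert 0 < np.max(np.abs(a - b)) < 0.1

    def test_invalid_n(self):
        with pytest.raises(ValueError, match="n must be"):
            simulate_spectra(default_brand_library()[0], 0)


class TestSimulateStudy:
    def test_design_counts(self, study_spectra):
        assert study_spectra.n_samples == 142
        assert study_spectra.n_points == 1557
        labels, counts = np.unique(study_spectra.labels, return_counts=True)
        assert dict(zip(labels.tolist(), counts.tolist())) == {
            "A": 48,
            "B": 46,
            "C": 48,
        }

    def test_grid_endpoints_uniform_spacing(self, study_spectra):
        wn = study_spectra.wavenumbers
        assert wn[0] == 10_000.0 and wn[-1] == 4_000.0
        np.testing.assert_allclose(np.diff(wn), np.diff(wn)[0], atol=1e-9)
        assert wn.size == 1557

    def test_deterministic(self):
        a = simulate_study(seed=11)
        b = simulate_study(seed=11)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_between_brand_distance_exceeds_within_brand(self):
        """After SNV, brand mean spectra are farther apart than the 95th
        percentile of within-brand sample-to-mean distances."""
        s = snv_transform(simulate_study(seed=5))
        X, labels = s.absorbance, s.labels
        means = {c: X[labels == c].mean(axis=0) for c in "ABC"}
        within = []
        for c in "ABC":
            d = np.linalg.norm(X[labels == c] - means[c], axis=1)
            within.append(np.quantile(d, 0.95))
        between = min(
            np.linalg.norm(means[a] - means[b])
            for a, b in [("A", "B"), ("A", "C"), ("B", "C")]
        )
        assert between > max(within)

    def test_batch_effects_change_output_only_when_enabled(self):
        plain = simulate_study(seed=2)
        again = simulate_study(seed=2, batch_effects=False)
        np.testing.assert_array_equal(plain.absorbance, again.absorbance)
        batched = simulate_study(seed=2, batch_effects=True)
        assert np.max(np.abs(batched.absorbance - plain.absorbance)) > 0


def test_brand_library_round_trip(tmp_path):
    from nirdd.synthetic import load_brand_library, save_brand_library

    lib = default_brand_library(separation=0.7)
    path = tmp_path / "recipes.json"
    save_brand_library(lib, path)
    back = load_brand_library(path)
    assert [r.name for r in back] == [r.name for r in lib]
    for a, b in zip(lib, back):
        np.testing.assert_array_equal(a.band_amplitudes, b.band_amplitudes)
        assert a.scatter_factor_range == b.scatter_factor_range
    # the reloaded library generates identical spectra
    x1 = simulate_spectra(lib[1], 3, seed=9).absorbance
    x2 = simulate_spectra(back[1], 3, seed=9).absorbance
    np.testing.assert_array_equal(x1, x2)
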