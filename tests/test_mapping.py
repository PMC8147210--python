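"""Pixel-wise moisture maps, median filtering, rendering and decisions."""

from dataclasses import replace

import numpy as np
import pytest

import feedcube as fc
from feedcube.errors import DecisionError, DomainError, ModelCompatibilityError
from feedcube.hypercube_io import Hypercube


@pytest.fixture(scope="module")
def trained_setup():
    """A raw-preprocessing model trained on noise-free generator spectra."""
    grid = fc.make_grid(894.0, 2504.0, 80)
    rng = np.random.default_rng(21)
    moistures = rng.uniform(0.05, 0.7, 60)
    X = fc.synth_spectra_matrix(
        moistures, grid, seed=2, noise_floor=0.0,
        scatter_offset_range=(0.0, 0.0), scatter_slope_range=(1.0, 1.0),
    )
    table = fc.SpectraTable(X, grid, 100 * moistures)
    sub_idx = fc.subrange_indices(grid, 894.0, 1917.0)
    sub = table.subset_bands(sub_idx)
    model = fc.fit_pls(sub.X, sub.y, 2)
    model.method = fc.fit_preprocess(fc.PreprocessMethod(kind="raw"))
    model.grid = sub.grid
    model.band_indices = sub_idx
    return grid, model


def _homogeneous_masked_cube(grid, m=0.33):
    cfg = fc.SceneConfig(
        height=32, width=32, disk_radius=10, grid=grid, noise_floor=0.0,
        field_amplitude=0.0, scatter_offset_range=(0.0, 0.0),
        scatter_slope_range=(1.0, 1.0), seed=4,
    )
    cube, white, dark, truth, true_mask = fc.synth_scene(m, cfg)
    refl = fc.calibrate(cube, fc.ReferencePanel(white, dark))
    return fc.apply_mask(refl, fc.build_mask(refl)), true_mask


class TestPredictMap:
    def test_homogeneous_scene_maps_to_sample_moisture(self, trained_setup):
        grid, model = trained_setup
        masked, _ = _homogeneous_masked_cube(grid, m=0.33)
        mmap = fc.predict_map(masked, model)
        assert np.nanstd(mmap.values[mmap.mask]) < 1e-6
        assert mmap.masked_mean == pytest.approx(33.0, abs=0.5)

    def test_map_mean_equals_tabular_prediction_for_raw(self, trained_setup):
        """With linear (raw) preprocessing the masked map mean is exactly the
        prediction on the masked mean spectrum."""
        grid, model = trained_setup
        masked, _ = _homogeneous_masked_cube(grid)
        mmap = fc.predict_map(masked, model)
        tabular = fc.predict(
            model, fc.mean_spectrum(masked)[model.band_indices]
        )
        assert mmap.masked_mean == pytest.approx(float(tabular), abs=1e-6)

    def test_background_is_nan_sentinel(self, trained_setup):
        grid, model = trained_setup
        masked, _ = _homogeneous_masked_cube(grid)
        mmap = fc.predict_map(masked, model)
        assert np.isnan(mmap.values[~mmap.mask]).all()

    def test_all_background_cube_maps_to_sentinels_only(self, trained_setup):
        grid, model = trained_setup
        sub_count = grid.count
        cube = Hypercube(
            np.full((8, 8, sub_count), 0.12), grid, state="masked_reflectance",
            mask=np.zeros((8, 8), bool),
        )
        mmap = fc.predict_map(cube, model)
        assert np.isnan(mmap.values).all()

    def test_grid_mismatch_rejected(self, trained_setup):
        _, model = trained_setup
        other = fc.make_grid(894.0, 2504.0, 40)
        cube = Hypercube(
            np.full((8, 8, 40), 0.5), other, state="masked_reflectance",
            mask=np.ones((8, 8), bool),
        )
        with pytest.raises(ModelCompatibilityError):
            fc.predict_map(cube, model)


class TestMedianFilter:
    def test_constant_map_unchanged(self):
        mask = np.ones((6, 6), bool)
        mmap = fc.MoistureMap(np.where(mask, 30.0, np.nan), mask)
        out = fc.median_filter_3x3(mmap)
        np.testing.assert_allclose(out.values[mask], 30.0)

    def test_single_impulse_removed(self):
        mask = np.ones((7, 7), bool)
        values = np.full((7, 7), 30.0)
        values[3, 3] += 50.0
        out = fc.median_filter_3x3(fc.MoistureMap(values, mask))
        assert out.values[3, 3] == pytest.approx(30.0)

    def test_matches_brute_force_masked_median(self):
        """Edge and mask-boundary pixels use only in-mask neighbours."""
        rng = np.random.default_rng(6)
        mask = rng.uniform(size=(12, 12)) > 0.3
        values = np.where(mask, rng.uniform(10, 60, (12, 12)), np.nan)
        out = fc.median_filter_3x3(fc.MoistureMap(values, mask))
        for y in range(12):
            for x in range(12):
                if not mask[y, x]:
                    assert np.isnan(out.values[y, x])
                    continue
                window = [
                    values[yy, xx]
                    for yy in range(max(0, y - 1), min(12, y + 2))
                    for xx in range(max(0, x - 1), min(12, x + 2))
                    if mask[yy, xx]
                ]
                assert out.values[y, x] == pytest.approx(np.median(window), abs=1e-12)

    def test_never_exceeds_window_extremes(self):
        rng = np.random.default_rng(8)
        mask = np.ones((10, 10), bool)
        values = rng.uniform(5, 70, (10, 10))
        out = fc.median_filter_3x3(fc.MoistureMap(values, mask))
        assert out.values[mask].max() <= values.max()
        assert out.values[mask].min() >= values.min()


class TestRenderMap:
    @pytest.fixture()
    def example_map(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        rng = np.random.default_rng(3)
        values = np.where(mask, rng.uniform(15, 55, (20, 20)), np.nan)
        return fc.MoistureMap(values, mask)

    def test_render_deterministic_bytes(self, tmp_path, example_map):
        a = fc.render_map(example_map, tmp_path / "a.png")
        b = fc.render_map(example_map, tmp_path / "b.png")
        assert a.read_bytes() == b.read_bytes()
        assert a.stat().st_size > 0

    def test_invalid_display_range_rejected(self, tmp_path, example_map):
        with pytest.raises(DomainError):
            fc.render_map(example_map, tmp_path / "c.png", display_range=(50.0, 10.0))

    def test_clipping_to_display_range(self, tmp_path, example_map):
        """Values at/beyond the range ends render to the colormap endpoints."""
        import matplotlib.pyplot as plt
        from PIL import Image

        lo_map = fc.MoistureMap(
            np.where(example_map.mask, -10.0, np.nan), example_map.mask
        )
        path = fc.render_map(lo_map, tmp_path / "lo.png", display_range=(0.0, 80.0))
        img = np.asarray(Image.open(path).convert("RGB")) / 255.0
        cmap_start = np.array(plt.get_cmap("viridis")(0.0))[:3]
        # some pixel block must carry the colormap start colour
        dist = np.abs(img - cmap_start).sum(axis=2)
        assert (dist < 0.05).any()


class TestDecisions:
    @pytest.mark.parametrize(
        "value, expected",
        [(45.0, "retreat_high"), (15.0, "retreat_low"), (30.0, "accept"),
         (20.0, "accept"), (40.0, "accept")],
    )
    def test_rule_examples(self, value, expected):
        assert fc.classify_batch(value) == expected

    def test_map_decision_uses_masked_mean(self):
        mask = np.ones((4, 4), bool)
        mmap = fc.MoistureMap(np.full((4, 4), 45.0), mask)
        assert fc.classify_batch(mmap) == "retreat_high"

    def test_monotone_over_moisture_sweep(self):
        """Raising moisture never moves the label backwards."""
        order = {"retreat_low": 0, "accept": 1, "retreat_high": 2}
        labels = [order[fc.classify_batch(m)] for m in np.linspace(0, 80, 161)]
        assert all(a <= b for a, b in zip(labels, labels[1:]))

    def test_empty_map_rejected(self):
        mmap = fc.MoistureMap(np.full((3, 3), np.nan), np.zeros((3, 3), bool))
        with pytest.raises(DecisionError):
            fc.classify_batch(mmap)

    def test_invalid_rule_rejected(self):
        with pytest.raises(DomainError):
            fc.DecisionRule(low_cut=40.0, high_cut=20.0)
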