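import numpy as np
import pytest

from conftest import make_params
from cropsail.errors import LayoutError, SchemaError
from cropsail.imagery import (
    BAND_ORDER,
    PlotDefinition,
    ReflectanceMap,
    background_correct,
    background_mask,
    default_soil_bands,
    ndvi_map,
    plot_reflectance,
    synth_field,
)
from cropsail.rtm import PlateSailModel, builtin_micasense_bands, resample_bands


def const_map(values, shape=(6, 6)):
    return ReflectanceMap(np.broadcast_to(np.asarray(values, float),
                                          (*shape, 5)).copy())


class TestNdvi:
    def test_equal_bands_give_zero(self):
        m = const_map([0.1, 0.1, 0.3, 0.3, 0.1])
        assert np.allclose(ndvi_map(m), 0.0)

    def test_hand_value(self):
        m = const_map([0, 0, 0.1, 0.5, 0])
        assert np.allclose(ndvi_map(m), (0.5 - 0.1) / 0.6)

    def test_zero_denominator_is_missing(self):
        m = const_map([0.2, 0.2, 0.0, 0.0, 0.2])
        assert np.all(np.isnan(ndvi_map(m)))


class TestBackgroundMask:
    def test_all_vegetation_above_threshold(self):
        mask = background_mask(np.full((4, 4), 0.9), 0.75)
        assert mask.all()

    def test_exactly_at_threshold_counts_as_vegetation(self):
        assert background_mask(np.array([[0.75]]), 0.75)[0, 0]

    def test_checkerboard_half_vegetation(self):
        ndvi = np.indices((4, 4)).sum(axis=0) % 2 * 0.4 + 0.4  # 0.4 / 0.8
        mask = background_mask(ndvi, 0.5)
        assert mask.sum() == 8

    def test_missing_ndvi_is_background(self):
        mask = background_mask(np.array([[np.nan, 0.8]]), 0.5)
        assert not mask[0, 0] and mask[0, 1]

    def test_monotone_in_threshold(self, rng):
        ndvi = rng.uniform(-1, 1, size=(10, 10))
        counts = [background_mask(ndvi, t).sum() for t in (-0.5, 0.0, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBackgroundCorrect:
    SOIL = np.array([0.1, 0.12, 0.15, 0.2, 0.17])

    def test_all_vegetation_untouched(self):
        m = const_map([0.2, 0.3, 0.1, 0.5, 0.3])
        out = background_correct(m, np.ones((6, 6), bool), self.SOIL)
        assert np.array_equal(out.data, m.data)

    def test_all_background_becomes_soil(self):
        m = const_map([0.2, 0.3, 0.1, 0.5, 0.3])
        out = background_correct(m, np.zeros((6, 6), bool), self.SOIL)
        assert np.allclose(out.data, self.SOIL)

    def test_mixed_mask_vegetation_bit_identical(self, rng):
        m = ReflectanceMap(rng.uniform(0, 1, size=(5, 5, 5)))
        mask = rng.random((5, 5)) < 0.5
        out = background_correct(m, mask, self.SOIL)
        assert np.array_equal(out.data[mask], m.data[mask])
        assert np.allclose(out.data[~mask], self.SOIL)

    def test_idempotent(self, rng):
        m = ReflectanceMap(rng.uniform(0, 1, size=(5, 5, 5)))
        mask = rng.random((5, 5)) < 0.5
        once = background_correct(m, mask, self.SOIL)
        twice = background_correct(once, mask, self.SOIL)
        assert np.array_equal(once.data, twice.data)

    def test_band_count_mismatch(self):
        with pytest.raises(SchemaError):
            background_correct(const_map([0.1] * 5), np.ones((6, 6), bool),
                               np.array([0.1, 0.2]))


class TestPlotReflectance:
    def test_constant_map(self):
        vals = [0.2, 0.3, 0.1, 0.5, 0.3]
        m = const_map(vals, shape=(8, 8))
        p = PlotDefinition("p1", 1, 5, 2, 6)
        assert np.allclose(plot_reflectance(m, p), vals)

    def test_hand_computed_mean(self):
        data = np.zeros((4, 4, 5))
        data[..., 3] = [[0.1, 0.2, 0, 0], [0.3, 0.4, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]]
        m = ReflectanceMap(data)
        p = PlotDefinition("p", 0, 2, 0, 2)
        assert plot_reflectance(m, p)[3] == pytest.approx(0.25)

    def test_trim_restricts_to_inner_pixels(self):
        data = np.zeros((4, 4, 5))
        data[..., 0] = 1.0
        data[1:3, 1:3, 0] = 0.5
        m = ReflectanceMap(data)
        p = PlotDefinition("p", 0, 4, 0, 4, trim=1)
        assert plot_reflectance(m, p)[0] == pytest.approx(0.5)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(LayoutError):
            plot_reflectance(const_map([0.1] * 5), PlotDefinition("p", 0, 9, 0, 3))

    def test_empty_after_trim_rejected(self):
        with pytest.raises(LayoutError):
            plot_reflectance(const_map([0.1] * 5), PlotDefinition("p", 0, 2, 0, 2, trim=1))

    def test_mean_within_band_extremes(self, rng):
        m = ReflectanceMap(rng.uniform(0, 1, size=(10, 10, 5)))
        p = PlotDefinition("p", 2, 8, 1, 7, trim=1)
        means = plot_reflectance(m, p)
        sub = m.data[3:7, 2:6]
        for b in range(5):
            assert sub[..., b].min() <= means[b] <= sub[..., b].max()


class TestSynthField:
    def test_single_plot_round_trip(self):
        params = make_params(LAI=4.0)
        plots = [PlotDefinition("a", 2, 8, 2, 8, trim=1)]
        rmap, truth = synth_field(plots, [params], shape=(10, 10), seed=0)
        expected = resample_bands(
            PlateSailModel().reflectance(params), builtin_micasense_bands())
        assert np.allclose(plot_reflectance(rmap, plots[0]), expected, atol=1e-10)
        assert truth[0]["LAI"] == 4.0

    def test_gap_pixels_are_soil(self):
        plots = [PlotDefinition("a", 0, 3, 0, 3)]
        rmap, _ = synth_field(plots, [make_params()], shape=(6, 6), seed=0)
        assert np.allclose(rmap.data[4, 4], default_soil_bands())

    def test_overlap_rejected(self):
        plots = [PlotDefinition("a", 0, 4, 0, 4), PlotDefinition("b", 2, 6, 2, 6)]
        with pytest.raises(LayoutError):
            synth_field(plots, [make_params(), make_params()], shape=(8, 8))

    def test_seed_deterministic(self):
        plots = [PlotDefinition("a", 0, 4, 0, 4)]
        a, _ = synth_field(plots, [make_params()], (6, 6), seed=3,
                           vegetation_fraction=0.7)
        b, _ = synth_field(plots, [make_params()], (6, 6), seed=3,
                           vegetation_fraction=0.7)
        assert np.array_equal(a.data, b.data)
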