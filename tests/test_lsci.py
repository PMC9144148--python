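"""Speckle-contrast processing chain and safety classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from renoperf import lsci
from renoperf.lsci import (
    IRREVERSIBLE,
    PHYSIOLOGICAL,
    REVERSIBLE,
    ROISpec,
)

from conftest import brute_force_contrast


class TestSpatialContrast:
    def test_constant_frame_has_zero_contrast(self):
        cmap = lsci.spatial_contrast(np.full((16, 16), 7.0))
        assert not cmap.mask.any()
        np.testing.assert_array_equal(cmap.values, 0.0)

    @given(
        hnp.arrays(
            dtype=np.int64,
            shape=(8, 8),
            elements=st.integers(min_value=1, max_value=255),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_per_window_double_loop(self, frame):
        cmap = lsci.spatial_contrast(frame.astype(float), 5)
        oracle = brute_force_contrast(frame.astype(float), 5)
        np.testing.assert_allclose(cmap.values, oracle, rtol=1e-9, atol=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        frame = rng.uniform(1.0, 100.0, (16, 16))
        base = lsci.spatial_contrast(frame).values
        scaled = lsci.spatial_contrast(c * frame).values
        np.testing.assert_allclose(scaled, base, rtol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            lsci.spatial_contrast(np.ones((8, 8)), 4)

    def test_all_zero_frame_fully_masked_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            cmap = lsci.spatial_contrast(np.zeros((8, 8)))
        assert cmap.mask.all()

    def test_window_default_is_five(self):
        cmap = lsci.spatial_contrast(np.ones((8, 8)))
        assert cmap.window_px == 5


class TestAverageContrast:
    def _cmap(self, value, shape=(6, 6)):
        return lsci.ContrastMap(
            np.full(shape, float(value)), np.zeros(shape, bool), 5
        )

    def test_mean_of_identical_maps_is_identity(self):
        maps = [self._cmap(0.7) for _ in range(25)]
        avg = lsci.average_contrast(maps)
        np.testing.assert_allclose(avg.values, 0.7)
        assert avg.n_frames_averaged == 25

    def test_arithmetic_mean_of_constants(self):
        maps = [self._cmap(v) for v in range(1, 26)]
        avg = lsci.average_contrast(maps, n=25)
        np.testing.assert_allclose(avg.values, 13.0)

    def test_mask_union(self):
        a = self._cmap(1.0)
        b = self._cmap(2.0)
        b.mask[0, 0] = True
        avg = lsci.average_contrast([a, b], n=2)
        assert avg.mask[0, 0] and not avg.mask[1, 1]

    def test_too_few_or_mismatched_maps_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            lsci.average_contrast([self._cmap(1.0)] * 10, n=25)
        with pytest.raises(ValueError, match="shape"):
            lsci.average_contrast(
                [self._cmap(1.0), self._cmap(1.0, shape=(7, 7))], n=2
            )


class TestContrastToFlow:
    @pytest.mark.parametrize("k,flow", [(1.0, 1.0), (0.5, 4.0), (0.1, 100.0)])
    def test_inverse_square_law(self, k, flow):
        cmap = lsci.ContrastMap(np.full((6, 6), k), np.zeros((6, 6), bool), 5)
        fmap = lsci.contrast_to_flow(cmap)
        np.testing.assert_allclose(fmap.values, flow)

    def test_zero_contrast_pixels_masked_and_counted(self):
        values = np.full((6, 6), 0.5)
        values[2, 3] = 0.0
        cmap = lsci.ContrastMap(values, np.zeros((6, 6), bool), 5)
        fmap = lsci.contrast_to_flow(cmap)
        assert fmap.mask[2, 3]
        assert fmap.n_zero_contrast == 1


class TestSmoothFlow:
    def test_constant_map_unchanged(self):
        fmap = lsci.FlowMap(np.full((32, 32), 3.0), np.zeros((32, 32), bool))
        out = lsci.smooth_flow(fmap, 7.0)
        np.testing.assert_allclose(out.values, 3.0, rtol=1e-12)

    def test_impulse_response_is_gaussian_kernel(self):
        n, sigma = 65, 3.0
        values = np.zeros((n, n))
        values[n // 2, n // 2] = 1.0
        fmap = lsci.FlowMap(values, np.zeros((n, n), bool))
        out = lsci.smooth_flow(fmap, sigma)
        oracle = ndimage.gaussian_filter(values, sigma, mode="reflect")
        np.testing.assert_allclose(out.values, oracle)
        # direct kernel evaluation at the centre
        x = np.arange(n) - n // 2
        g = np.exp(-0.5 * (x / sigma) ** 2)
        kernel_2d = np.outer(g, g) / np.outer(g, g).sum()
        assert out.values[n // 2, n // 2] == pytest.approx(
            kernel_2d[n // 2, n // 2], rel=1e-3
        )

    def test_total_conserved_for_positive_map(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.5, 2.0, (64, 64))
        fmap = lsci.FlowMap(values, np.zeros((64, 64), bool))
        out = lsci.smooth_flow(fmap, 7.0)
        assert out.values.sum() == pytest.approx(values.sum(), rel=1e-6)


class TestROIStatistics:
    def test_constant_roi(self):
        fmap = lsci.FlowMap(np.full((20, 20), 5.0), np.zeros((20, 20), bool))
        mean, sd = lsci.roi_statistics(fmap, ROISpec(2, 2, 10, 10))
        assert (mean, sd) == (5.0, 0.0)

    def test_hand_computed_sample_sd(self):
        values = np.array([[1.0, 2.0], [3.0, 4.0]])
        fmap = lsci.FlowMap(values, np.zeros((2, 2), bool))
        mean, sd = lsci.roi_statistics(fmap, ROISpec(0, 0, 2, 2))
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.sqrt(5.0 / 3.0))  # ~1.2910

    def test_default_roi_is_200_square(self):
        roi = ROISpec()
        assert (roi.height, roi.width) == (200, 200)

    def test_roi_outside_image_rejected(self):
        fmap = lsci.FlowMap(np.ones((50, 50)), np.zeros((50, 50), bool))
        with pytest.raises(ValueError, match="fit"):
            lsci.roi_statistics(fmap, ROISpec(0, 0, 60, 60))

    def test_fully_masked_roi_rejected(self):
        fmap = lsci.FlowMap(np.ones((20, 20)), np.ones((20, 20), bool))
        with pytest.raises(ValueError, match="unmasked"):
            lsci.roi_statistics(fmap, ROISpec(0, 0, 10, 10))


class TestNormalizeAndClassify:
    def test_percent_of_baseline(self):
        series = lsci.normalize_to_baseline(
            [("baseline", 2.0, 0.1), ("t", 1.0, 0.1)], "baseline"
        )
        assert series.percent_of_baseline == {"baseline": 100.0, "t": 50.0}

    def test_baseline_maps_to_exactly_100(self):
        series = lsci.normalize_to_baseline([("baseline", 0.37, 0.0)], "baseline")
        assert series.percent_of_baseline["baseline"] == 100.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            lsci.normalize_to_baseline([("baseline", 0.0, 0.0)], "baseline")

    @pytest.mark.parametrize(
        "percents,expected",
        [
            ({"baseline": 100.0, "15min": 85.0, "24h": 95.0}, PHYSIOLOGICAL),
            ({"baseline": 100.0, "15min": 47.0, "24h": 53.0}, IRREVERSIBLE),
            ({"baseline": 100.0, "15min": 60.0, "24h": 90.0}, REVERSIBLE),
            # inclusive boundary: exactly 80 % of baseline is still normal
            ({"baseline": 100.0, "15min": 80.0, "24h": 80.0}, PHYSIOLOGICAL),
            ({"baseline": 100.0, "15min": 79.999, "24h": 80.0}, REVERSIBLE),
            ({"baseline": 100.0, "15min": 100.0, "24h": 79.999}, IRREVERSIBLE),
        ],
    )
    def test_three_way_rule_with_boundaries(self, percents, expected):
        series = lsci.FlowTimeSeries(
            [(k, v, 0.0) for k, v in percents.items()], "baseline", percents
        )
        assert lsci.classify_flow_response(series, "24h", 20.0).label == expected

    def test_missing_final_label_rejected(self):
        series = lsci.normalize_to_baseline([("baseline", 1.0, 0.0)], "baseline")
        with pytest.raises(ValueError, match="final"):
            lsci.classify_flow_response(series, "24h")


class TestRelativeChange:
    def test_size_and_dose_headline_values(self):
        assert round(lsci.relative_change(3.1, 4.0, "old")) == 29
        assert round(lsci.relative_change(20e6, 10e6, "old")) == -50

    def test_no_change_is_zero(self):
        assert lsci.relative_change(5.0, 5.0, "old") == 0.0
        assert lsci.relative_change(5.0, 5.0, "new") == 0.0

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError):
            lsci.relative_change(0.0, 1.0)
        with pytest.raises(ValueError):
            lsci.relative_change(1.0, 1.0, reference="mid")
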