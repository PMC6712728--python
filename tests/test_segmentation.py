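import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qluss.errors import ConfigurationError, DegenerateClusteringError
from qluss.phantom import Band, PhantomSpec, generate_frame, random_spec
from qluss.segmentation import (
    BinaryMask,
    ContrastWarning,
    SegmentationConfig,
    adjust_contrast,
    asf_filter,
    detect_bline_columns,
    frame_bline_percent,
    kmeans_binarize,
    run_pipeline,
)

CFG = SegmentationConfig()
from _oracles import brute_force_best_threshold_mask  # noqa: E402


class TestConfig:
    def test_default_schedule_ends_at_gap_plus_one(self):
        assert CFG.schedule == (3, 5, 7, 9, 11)
        assert SegmentationConfig(asf_max_gap=4).schedule == (3, 5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"low_percentile": 99, "high_percentile": 1},
            {"white_fraction_threshold": 0.0},
            {"depth_fraction": 1.5},
            {"asf_max_gap": 0},
            {"kmeans_k": 3},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SegmentationConfig(**kwargs)

    def test_digest_stable_and_sensitive(self):
        assert CFG.digest() == SegmentationConfig().digest()
        assert CFG.digest() != SegmentationConfig(asf_max_gap=8).digest()


class TestContrast:
    def test_full_range_roi_nearly_unchanged(self, roi_factory, rng):
        px = rng.integers(0, 256, size=(100, 100), dtype=np.uint8)
        px[0, :2] = (0, 255)  # pin the extremes
        out = adjust_contrast(roi_factory(px), CFG)
        # interior values move by at most the 1%/99% clip quantization
        assert np.abs(out.pixels.astype(int) - px.astype(int)).mean() < 6

    def test_constant_roi_warns_and_passes_through(self, roi_factory):
        px = np.full((40, 40), 77, dtype=np.uint8)
        with pytest.warns(ContrastWarning):
            out = adjust_contrast(roi_factory(px), CFG)
        np.testing.assert_array_equal(out.pixels, px)
        assert out.contrast_warning

    def test_two_value_roi_maps_to_extremes(self, roi_factory):
        px = np.full((10, 100), 50, dtype=np.uint8)
        px[:, 90:] = 200  # 10% of pixels
        out = adjust_contrast(roi_factory(px), CFG)
        assert np.all(out.pixels[:, :90] == 0)
        assert np.all(out.pixels[:, 90:] == 255)


class TestKmeansBinarize:
    def test_bimodal_split(self, roi_factory):
        px = np.full((10, 10), 10, dtype=np.uint8)
        px[5:] = 240
        mask = kmeans_binarize(roi_factory(px), CFG)
        assert mask.stage == "kmeans"
        np.testing.assert_array_equal(mask.pixels, px == 240)

    def test_four_level_roi_matches_exhaustive_minimum(self, roi_factory):
        # equally frequent {0, 100, 101, 255}: the within-SS-minimal split is
        # {0, 100, 101} | {255} (SS 6734 per unit count vs 16858 for a split
        # between 100 and 101)
        px = np.tile(np.array([0, 100, 101, 255], dtype=np.uint8), (8, 8))
        mask = kmeans_binarize(roi_factory(px), CFG)
        np.testing.assert_array_equal(mask.pixels, px == 255)
        np.testing.assert_array_equal(mask.pixels, brute_force_best_threshold_mask(px))

    def test_single_value_roi_raises(self, roi_factory):
        with pytest.raises(DegenerateClusteringError, match="contrast"):
            kmeans_binarize(roi_factory(np.full((8, 8), 9, dtype=np.uint8)), CFG)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        if np.unique(px).size < 2:
            return
        from qluss.frames_io import SubPleuralROI

        mask = kmeans_binarize(SubPleuralROI(px, 0, 0), CFG)
        np.testing.assert_array_equal(mask.pixels, brute_force_best_threshold_mask(px))

    def test_white_class_is_higher_centroid(self, roi_factory, rng):
        px = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        mask = kmeans_binarize(roi_factory(px), CFG)
        assert px[mask.pixels].mean() > px[~mask.pixels].mean()


class TestASF:
    def test_axial_gap_up_to_10px_closed(self):
        for gap in (1, 4, 8, 10):
            col = np.ones((60, 5), dtype=bool)
            col[:, :2] = False
            col[25 : 25 + gap, 2] = False
            out = asf_filter(BinaryMask(col, "kmeans"), CFG)
            assert out.stage == "asf"
            assert np.all(out.pixels[:, 2]), f"gap of {gap} not closed"

    def test_wide_gap_not_closed(self):
        col = np.zeros((80, 5), dtype=bool)
        col[:30, 2] = True
        col[30 + 14 :, 2] = True
        out = asf_filter(BinaryMask(col, "kmeans"), CFG)
        assert not np.all(out.pixels[:, 2])

    def test_isolated_speck_removed(self):
        m = np.zeros((40, 40), dtype=bool)
        m[20, 20] = True
        out = asf_filter(BinaryMask(m, "kmeans"), CFG)
        assert not out.pixels.any()

    def test_horizontal_bridge_severed_columns_preserved(self):
        # two tall columns joined by a 1-pixel-tall bridge on a 15x9 grid
        m = np.zeros((15, 9), dtype=bool)
        m[:, 1] = True
        m[:, 7] = True
        m[7, 2:7] = True
        out = asf_filter(BinaryMask(m, "kmeans"), CFG)
        assert np.all(out.pixels[:, 1]) and np.all(out.pixels[:, 7])
        assert not out.pixels[7, 3:6].any()

    def test_full_columns_are_fixed_points(self):
        m = np.zeros((50, 8), dtype=bool)
        m[:, 3] = True
        out = asf_filter(BinaryMask(m, "kmeans"), CFG)
        np.testing.assert_array_equal(out.pixels, m)

    def test_idempotent(self, rng):
        for _ in range(10):
            m = rng.random((60, 30)) < rng.uniform(0.2, 0.8)
            once = asf_filter(BinaryMask(m, "kmeans"), CFG)
            twice = asf_filter(BinaryMask(once.pixels, "kmeans"), CFG)
            np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestColumnScan:
    def test_window_counting_and_inclusive_threshold(self):
        # 100-row ROI, window = 70 rows; 35 white rows -> 0.5, flagged;
        # 34 -> not flagged
        m = np.zeros((100, 3), dtype=bool)
        m[:35, 0] = True
        m[:34, 1] = True
        m[:100, 2] = True
        det = detect_bline_columns(BinaryMask(m, "asf"), CFG)
        np.testing.assert_allclose(det.white_fraction, [0.5, 34 / 70, 1.0])
        assert det.is_bline.tolist() == [True, False, True]

    def test_white_below_window_ignored(self):
        m = np.zeros((100, 1), dtype=bool)
        m[70:] = True  # bottom 30% only
        det = detect_bline_columns(BinaryMask(m, "asf"), CFG)
        assert det.white_fraction[0] == 0.0 and not det.is_bline[0]

    def test_threshold_monotonicity(self, rng):
        m = rng.random((80, 40)) < 0.5
        loose = detect_bline_columns(BinaryMask(m, "asf"), SegmentationConfig(white_fraction_threshold=0.3))
        strict = detect_bline_columns(BinaryMask(m, "asf"), SegmentationConfig(white_fraction_threshold=0.7))
        assert loose.is_bline.sum() >= strict.is_bline.sum()


class TestFramePercent:
    @pytest.mark.parametrize("flagged,total,expected", [(0, 200, 0.0), (200, 200, 100.0), (80, 200, 40.0)])
    def test_percentage_arithmetic(self, flagged, total, expected):
        from qluss.segmentation import ColumnDetection

        det = ColumnDetection(
            white_fraction=np.linspace(0, 1, total),
            is_bline=np.arange(total) < flagged,
        )
        assert frame_bline_percent(det).bline_percent == expected


class TestPipeline:
    def test_noiseless_phantom_percent_recovered_exactly(self):
        spec = PhantomSpec(
            width=200, bands=(Band(40, 20), Band(100, 20), Band(160, 20))
        )  # 60/200 columns = 30%
        frame, truth = generate_frame(spec)
        assert truth.true_bline_percent == 30.0
        assert run_pipeline(frame).bline_percent == 30.0

    def test_all_dark_phantom_is_zero(self):
        frame, _ = generate_frame(PhantomSpec())
        assert run_pipeline(frame).bline_percent == 0.0

    def test_full_width_coalescent_band_is_100(self):
        spec = PhantomSpec(width=64, bands=(Band(32, 64),))
        frame, truth = generate_frame(spec)
        assert truth.true_bline_percent == 100.0
        assert run_pipeline(frame).bline_percent == 100.0

    def test_deterministic_bit_identical(self):
        spec = PhantomSpec(bands=(Band(60, 30),), speckle_sigma=0.1, seed=3)
        frame, _ = generate_frame(spec)
        r1 = run_pipeline(frame, keep_intermediates=True)
        r2 = run_pipeline(frame, keep_intermediates=True)
        assert r1.bline_percent == r2.bline_percent
        np.testing.assert_array_equal(
            r1.intermediates["asf"].pixels, r2.intermediates["asf"].pixels
        )

    def test_widening_bands_never_decreases_percent(self):
        prev = -1.0
        for width in (10, 20, 40, 80):
            frame, _ = generate_frame(PhantomSpec(width=128, bands=(Band(64, width),)))
            pct = run_pipeline(frame).bline_percent
            assert pct >= prev
            prev = pct

    def test_ground_truth_column_set_recovered_on_random_noiseless_specs(self, rng):
        for _ in range(15):
            spec = random_spec(rng)
            frame, truth = generate_frame(spec)
            res = run_pipeline(frame, keep_intermediates=True)
            if not truth.column_mask.any():
                assert res.bline_percent == 0.0
                continue
            np.testing.assert_array_equal(
                res.intermediates["columns"].is_bline, truth.column_mask
            )

    def test_constant_roi_scores_zero(self):
        from qluss.frames_io import UltrasoundFrame

        frame = UltrasoundFrame(np.zeros((64, 64), dtype=np.uint8))
        assert run_pipeline(frame).bline_percent == 0.0

    def test_stage_errors_carry_stage_name(self):
        from qluss.errors import DegenerateROIError
        from qluss.frames_io import UltrasoundFrame

        frame = UltrasoundFrame(np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(DegenerateROIError) as err:
            run_pipeline(frame, pleural_row=60)
        assert any("pleural-line" in note for note in err.value.__notes__)
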