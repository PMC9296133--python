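import numpy as np
import pytest

from nedyn import importdyn
from nedyn.errors import (ConfigurationError, ContrastError, InputError,
                          NormalizationError, SegmentationError)
from nedyn.io import RegionSpec


def _disk_frame(shape=(128, 128), center=(64, 64), radius=20,
                fg=200.0, bg=50.0, noise_sd=0.0, seed=0):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    mask = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2
    frame = np.full(shape, bg) + (fg - bg) * mask
    if noise_sd:
        frame = frame + np.random.default_rng(seed).normal(0, noise_sd, shape)
    return frame, mask


class TestSegmentNucleus:
    def test_noisy_disk_overlap_above_0p9(self):
        frame, truth = _disk_frame(noise_sd=5.0, seed=1)
        region = importdyn.segment_nucleus(frame)
        got = region.to_mask(frame.shape)
        iou = (got & truth).sum() / (got | truth).sum()
        assert iou > 0.9

    def test_constant_frame_is_segmentation_error(self):
        with pytest.raises(SegmentationError, match="constant"):
            importdyn.segment_nucleus(np.full((32, 32), 7.0))

    def test_largest_component_wins(self):
        frame, big = _disk_frame(center=(40, 40), radius=20)
        small_frame, small = _disk_frame(center=(100, 100), radius=8)
        frame = np.maximum(frame, small_frame)
        got = importdyn.segment_nucleus(frame).to_mask(frame.shape)
        assert (got & big).sum() > 0.9 * big.sum()
        assert (got & small).sum() == 0


class TestNCRatio:
    def _setup(self, n_val=200.0, c_val=100.0, bg_val=50.0):
        frame = np.full((64, 64), c_val)
        frame[:20, :20] = bg_val
        nucleus_mask = np.zeros((64, 64), bool)
        nucleus_mask[40:50, 40:50] = True  # 100 px
        frame[nucleus_mask] = n_val
        nucleus = RegionSpec.polygon(
            [[40, 40], [49, 40], [49, 49], [40, 49]], mask=nucleus_mask)
        cyto = RegionSpec.box(30, 5, 20, 20)
        bg = RegionSpec.box(0, 0, 20, 20)
        return frame, nucleus, cyto, bg

    def test_printed_example(self):
        # N=200, C=100, bg=50, 100 px at 1 um/px: ((200-50)/(100-50))*100
        frame, nucleus, cyto, bg = self._setup()
        comp = importdyn.nc_ratio(frame, nucleus, cyto, bg, pixel_size_um=1.0)
        assert comp.nc_value == pytest.approx(300.0)
        assert comp.ratio == pytest.approx(3.0)

    def test_uniform_image_gives_area(self):
        frame, nucleus, cyto, bg = self._setup(n_val=100.0, bg_val=50.0)
        comp = importdyn.nc_ratio(frame, nucleus, cyto, bg, pixel_size_um=1.0)
        assert comp.ratio == pytest.approx(1.0)
        assert comp.nc_value == pytest.approx(comp.area_um2)

    def test_additive_offset_invariance(self):
        frame, nucleus, cyto, bg = self._setup()
        a = importdyn.nc_ratio(frame, nucleus, cyto, bg, 1.0)
        b = importdyn.nc_ratio(frame + 10.0, nucleus, cyto, bg, 1.0)
        assert b.nc_value == pytest.approx(a.nc_value, rel=1e-12)

    def test_multiplicative_gain_invariance(self):
        frame, nucleus, cyto, bg = self._setup()
        a = importdyn.nc_ratio(frame, nucleus, cyto, bg, 1.0)
        b = importdyn.nc_ratio(frame * 3.7, nucleus, cyto, bg, 1.0)
        assert b.nc_value == pytest.approx(a.nc_value, rel=1e-12)

    def test_degenerate_contrast(self):
        frame, nucleus, cyto, bg = self._setup(c_val=40.0, bg_val=50.0)
        with pytest.raises(ContrastError):
            importdyn.nc_ratio(frame, nucleus, cyto, bg, 1.0)

    def test_box_overlapping_nucleus_is_configuration_error(self):
        frame, nucleus, _, bg = self._setup()
        overlapping = RegionSpec.box(35, 35, 20, 20)
        with pytest.raises(ConfigurationError):
            importdyn.nc_ratio(frame, nucleus, overlapping, bg, 1.0)


class TestImportTrace:
    def test_round_trip_within_5pct(self, import_roundtrip):
        _, _, truth, trace = import_roundtrip
        rel = np.abs(trace.ratio - truth.ratio_true.to_numpy()) \
            / truth.ratio_true.to_numpy()
        assert np.nanmax(rel) < 0.05

    def test_anchor_time_arithmetic(self, import_roundtrip):
        params, stack, _, _ = import_roundtrip
        from nedyn import synth
        cyto, bg = synth.default_boxes(params)
        trace = importdyn.import_trace(stack, "reporter", "chromatin",
                                       ("furrow", 3), cyto, bg)
        assert trace.times_s[0] == -60.0
        assert trace.anchor_event == "furrow"

    def test_constant_stack_is_trace_error(self):
        from nedyn.errors import TraceError
        from nedyn.io import ImageStack
        stack = ImageStack(pixels=np.full((2, 4, 1, 64, 64), 5.0),
                           channels=["reporter", "chromatin"],
                           pixel_size_um=0.1, time_step_s=20.0)
        with pytest.raises(TraceError):
            importdyn.import_trace(stack, 0, 1, ("a", 0),
                                   RegionSpec.box(2, 2, 10, 10),
                                   RegionSpec.box(40, 40, 10, 10))


def _trace(values, dt=20.0, anchor=0):
    values = np.asarray(values, float)
    times = (np.arange(len(values)) - anchor) * dt
    return importdyn.ImportTrace(
        times_s=times, nc_value=values * 10.0, ratio=values,
        nuclear_mean=values, cyto_mean=np.ones_like(values),
        background=np.zeros_like(values), area_um2=np.full_like(values, 10.0),
        anchor_event="anaphase", anchor_frame=anchor)


class TestDetectOnset:
    def test_constructed_step(self):
        # flat baseline (tiny jitter) for 5 frames, step up at t = 40 s
        vals = [100, 101, 99, 100, 100, 200, 210, 220]
        tr = _trace(vals, dt=20.0, anchor=3)  # step index 5 -> t = 40 s
        assert importdyn.detect_onset(tr) == 40.0

    def test_flat_trace_has_no_onset(self):
        tr = _trace([100.0] * 10)
        assert importdyn.detect_onset(tr) is None

    def test_monotone_in_k_sd(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([100 + rng.normal(0, 1, 8),
                               np.linspace(105, 160, 12)])
        tr = _trace(vals)
        onsets = [importdyn.detect_onset(tr, k_sd=k) for k in (1, 3, 6, 12)]
        seen = [o for o in onsets if o is not None]
        assert seen == sorted(seen)
        # once None appears it stays None for larger k
        first_none = next((i for i, o in enumerate(onsets) if o is None),
                          len(onsets))
        assert all(o is None for o in onsets[first_none:])

    def test_too_short_trace(self):
        with pytest.raises(InputError):
            importdyn.detect_onset(_trace([1, 2, 3]))

    def test_generator_round_trip_within_one_frame(self, delayed_import_trace):
        params, _, trace = delayed_import_trace
        onset = importdyn.detect_onset(trace)
        assert onset is not None
        assert abs(onset - params.import_start_s) <= params.frame_interval_s


class TestNormalizeAndDifference:
    def test_single_trace(self):
        res = importdyn.normalize_and_difference([_trace([0.0, 50.0, 100.0])],
                                                 signal="ratio")
        np.testing.assert_allclose(res.average, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(res.differences, [0.5, 0.5])

    def test_averaging_identity(self):
        one = importdyn.normalize_and_difference([_trace([0, 5, 20])],
                                                 signal="ratio")
        two = importdyn.normalize_and_difference(
            [_trace([0, 5, 20]), _trace([0, 5, 20])], signal="ratio")
        np.testing.assert_allclose(one.average, two.average)

    def test_scale_free_normalization(self):
        res = importdyn.normalize_and_difference(
            [_trace([0.0, 100.0]), _trace([0.0, 200.0])], signal="ratio")
        np.testing.assert_allclose(res.normalized, [[0, 1], [0, 1]])
        np.testing.assert_allclose(res.average, [0, 1])
        np.testing.assert_allclose(res.differences, [1.0])

    def test_constant_trace_is_normalization_error(self):
        with pytest.raises(NormalizationError, match="trace 1"):
            importdyn.normalize_and_difference(
                [_trace([0, 1, 2]), _trace([5, 5, 5])], signal="ratio")
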