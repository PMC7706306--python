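import numpy as np
import pandas as pd
import pytest

from wiltlag import wilt_quantification as wq
from wiltlag.synthetic_data import ScenarioConfig, render_frames


def solid_frame(rgb, size=64):
    frame = np.zeros((size, size, 3), dtype=np.uint8)
    frame[:] = rgb
    return frame


def textured_pair(shift=(0, 0), size=144, seed=0):
    """A textured green square on grey, translated by (dy, dx) px in frame b."""
    rng = np.random.default_rng(seed)
    a = solid_frame((128, 128, 128), size)
    patch = np.stack(
        [
            rng.integers(10, 80, (24, 24)),
            rng.integers(150, 255, (24, 24)),
            rng.integers(10, 80, (24, 24)),
        ],
        axis=-1,
    ).astype(np.uint8)
    a[60:84, 60:84] = patch
    b = solid_frame((128, 128, 128), size)
    dy, dx = shift
    b[60 + dy : 84 + dy, 60 + dx : 84 + dx] = patch
    return a, b


class TestExg:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((0, 255, 0), 2.0), ((128, 128, 128), 0.0), ((255, 0, 0), -1.0), ((0, 0, 0), 0.0)],
    )
    def test_reference_pixels(self, rgb, expected):
        assert wq.exg_index(rgb) == pytest.approx(expected)

    def test_brightness_invariance(self):
        assert wq.exg_index((20, 60, 20)) == pytest.approx(wq.exg_index((60, 180, 60)))


class TestPlantMask:
    def test_grey_frame_all_false(self):
        assert not wq.plant_mask(solid_frame((90, 90, 90))).any()

    def test_green_frame_all_true(self):
        assert wq.plant_mask(solid_frame((0, 255, 0))).all()

    def test_matches_renderer_ground_truth(self, rendered_day):
        frame = rendered_day.frames.frames[50]
        gt = rendered_day.frames.true_plant_masks[50]
        assert np.array_equal(wq.plant_mask(frame), gt)


class TestEstimateFlow:
    def test_identical_frames_zero_field_exact(self):
        a, _ = textured_pair()
        flow = wq.estimate_flow(a, a, method="block_match")
        assert np.all(flow.u == 0.0) and np.all(flow.v == 0.0)

    @pytest.mark.parametrize("method", ["block_match", "dense_reference"])
    def test_known_integer_shift_recovered(self, method):
        a, b = textured_pair(shift=(2, 0))
        flow = wq.estimate_flow(a, b, method=method)
        interior_v = flow.v[65:79, 65:79]
        interior_u = flow.u[65:79, 65:79]
        assert np.median(interior_v) == pytest.approx(2.0, abs=0.3)
        assert np.median(interior_u) == pytest.approx(0.0, abs=0.3)

    @pytest.mark.parametrize("method", ["block_match", "dense_reference"])
    def test_output_dimensions_match_input(self, method):
        a, b = textured_pair(shift=(1, 1))
        flow = wq.estimate_flow(a, b, method=method)
        assert flow.u.shape == a.shape[:2] and flow.v.shape == a.shape[:2]

    def test_dimension_mismatch_rejected(self):
        a, _ = textured_pair()
        with pytest.raises(ValueError):
            wq.estimate_flow(a, a[:100], method="block_match")

    def test_unknown_method_rejected(self):
        a, _ = textured_pair()
        with pytest.raises(ValueError):
            wq.estimate_flow(a, a, method="farneback")

    def test_deepflow_capability_error_without_opencv(self):
        a, b = textured_pair(shift=(1, 0))
        try:
            import cv2  # noqa: F401

            has_cv2 = hasattr(cv2, "optflow")
        except ImportError:
            has_cv2 = False
        if has_cv2:
            flow = wq.estimate_flow(a, b, method="deepflow")
            assert flow.u.shape == a.shape[:2]
        else:
            with pytest.raises(wq.FlowBackendUnavailable):
                wq.estimate_flow(a, b, method="deepflow")


class TestHoofBins:
    def _mask(self, shape=(10, 10)):
        return np.ones(shape, dtype=bool)

    def test_uniform_upward_flow(self):
        flow = wq.FlowField(u=np.zeros((10, 10)), v=np.full((10, 10), -1.0))
        bins = wq.hoof_bins(flow, self._mask())
        assert bins.up_sum / bins.masked_pixel_count == pytest.approx(1.0)
        assert bins.down_sum == 0.0

    def test_symmetric_flow_splits_evenly(self):
        v = np.zeros((10, 10))
        v[:5] = 3.0
        v[5:] = -3.0
        bins = wq.hoof_bins(wq.FlowField(u=np.zeros((10, 10)), v=v), self._mask())
        assert bins.up_sum / bins.masked_pixel_count == pytest.approx(1.5)
        assert bins.down_sum / bins.masked_pixel_count == pytest.approx(1.5)

    def test_horizontal_flow_contributes_nothing(self):
        flow = wq.FlowField(u=np.full((10, 10), 5.0), v=np.zeros((10, 10)))
        bins = wq.hoof_bins(flow, self._mask())
        assert bins.up_sum == 0.0 and bins.down_sum == 0.0

    def test_empty_mask_rejected(self):
        flow = wq.FlowField(u=np.zeros((4, 4)), v=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            wq.hoof_bins(flow, np.zeros((4, 4), dtype=bool))

    def test_magnitude_weighting_uses_euclidean_norm(self):
        u = np.full((4, 4), 3.0)
        v = np.full((4, 4), 4.0)
        bins = wq.hoof_bins(wq.FlowField(u=u, v=v), self._mask((4, 4)))
        assert bins.down_sum / bins.masked_pixel_count == pytest.approx(5.0)


class TestDeltaWilt:
    @pytest.mark.parametrize(
        "up,down,expected", [(1.0, 0.0, 1.0), (0.7, 0.7, 0.0), (0.2, 0.5, -0.3)]
    )
    def test_per_pixel_difference(self, up, down, expected):
        bins = wq.HoofBins(up_sum=up * 100, down_sum=down * 100, masked_pixel_count=100)
        assert wq.delta_wilt(bins) == pytest.approx(expected)

    def test_scale_bound(self):
        rng = np.random.default_rng(0)
        flow = wq.FlowField(u=rng.normal(size=(20, 20)), v=rng.normal(size=(20, 20)))
        mask = rng.random((20, 20)) > 0.4
        bins = wq.hoof_bins(flow, mask)
        mean_mag = np.hypot(flow.u, flow.v)[mask].mean()
        assert abs(wq.delta_wilt(bins)) <= mean_mag + 1e-12


class TestWiltSeries:
    def _static_sequence(self, n=8):
        frame = solid_frame((128, 128, 128), 144)
        frame[40:80, 60:90] = (30, 200, 30)
        frames = np.stack([frame] * n)
        ts = pd.date_range("2018-04-06 09:00", periods=n, freq="min")
        return wq.ImageSequence(frames=frames, timestamps=ts)

    def test_static_sequence_zero_everywhere(self):
        out = wq.quantify_wilt_series(self._static_sequence(), w=5)
        assert len(out) == 3
        assert np.allclose(out["delta_wilt"], 0.0)

    def test_missing_partner_logged_as_gap(self):
        seq = self._static_sequence(8)
        keep = [0, 1, 2, 3, 4, 6, 7]  # drop frame at +5 min
        seq2 = wq.ImageSequence(frames=seq.frames[keep], timestamps=seq.timestamps[keep])
        out = wq.quantify_wilt_series(seq2, w=5)
        # t = +10 min lost its earlier partner (+5 min)
        assert seq.timestamps[5] not in out.index
        assert len(out.attrs["gaps"]) > 0

    def test_fewer_than_two_frames_rejected(self):
        seq = self._static_sequence(8)
        single = wq.ImageSequence(frames=seq.frames[:1], timestamps=seq.timestamps[:1])
        with pytest.raises(ValueError):
            wq.quantify_wilt_series(single, w=5)

    def test_rendered_wilting_event_scores_negative(self):
        cfg = ScenarioConfig(seed=0, sensor_noise_sd=0.0)
        idx = pd.date_range("2018-04-06 09:00", periods=10, freq="min")
        truth = pd.DataFrame(
            {"wilt_displacement": np.linspace(0.0, 6.0, 10)}, index=idx
        )
        seq = render_frames(truth, cfg, clouds=False)
        out = wq.quantify_wilt_series(seq, w=5, method="block_match")
        assert (out["delta_wilt"] < 0).all()

    def test_reversal_antisymmetry(self):
        # all-green frames (mask everywhere) with an interior textured patch
        # moving down 2 px: swapping frame order must flip delta_wilt's sign
        rng = np.random.default_rng(5)
        a = solid_frame((30, 200, 30), 144)
        patch_g = rng.integers(120, 255, (24, 24)).astype(np.uint8)
        a[60:84, 60:84, 1] = patch_g
        b = solid_frame((30, 200, 30), 144)
        b[62:86, 60:84, 1] = patch_g
        ts = pd.date_range("2018-04-06 09:00", periods=2, freq="min")
        fwd = wq.quantify_wilt_series(
            wq.ImageSequence(frames=np.stack([a, b]), timestamps=ts), w=1
        )
        rev = wq.quantify_wilt_series(
            wq.ImageSequence(frames=np.stack([b, a]), timestamps=ts), w=1
        )
        assert fwd["delta_wilt"].iloc[0] == pytest.approx(
            -rev["delta_wilt"].iloc[0], abs=1e-6
        )

    def test_clouds_do_not_change_delta_wilt(self):
        cfg = ScenarioConfig(seed=0, sensor_noise_sd=0.0)
        idx = pd.date_range("2018-04-06 09:00", periods=8, freq="min")
        truth = pd.DataFrame({"wilt_displacement": np.linspace(0, 3, 8)}, index=idx)
        with_clouds = wq.quantify_wilt_series(render_frames(truth, cfg, clouds=True), w=5)
        without = wq.quantify_wilt_series(render_frames(truth, cfg, clouds=False), w=5)
        assert np.allclose(
            with_clouds["delta_wilt"].to_numpy(), without["delta_wilt"].to_numpy(), atol=1e-6
        )


class TestFastPath:
    def test_delta_wilt_equals_negative_displacement_difference(self, sunny_dataset):
        from wiltlag.wilt_quantification import quantify_wilt_from_flows

        out = quantify_wilt_from_flows(sunny_dataset.flows)
        disp = sunny_dataset.truth["wilt_displacement"]
        for ts in out.index[:50]:
            expected = -(disp.loc[ts] - disp.loc[ts - pd.Timedelta(minutes=5)])
            assert out.loc[ts, "delta_wilt"] == pytest.approx(expected, abs=1e-12)
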