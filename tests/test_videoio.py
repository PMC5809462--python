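import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toipulse import videoio as vio


class TestBitplanes:
    def test_zero_frame_gives_zero_planes(self):
        planes = vio.decompose_bitplanes(np.zeros((4, 5, 3), np.uint8))
        assert len(planes) == 24
        assert all((p == 0).all() for p in planes.values())

    def test_saturated_frame_gives_one_planes(self):
        planes = vio.decompose_bitplanes(np.full((4, 5, 3), 255, np.uint8))
        assert all((p == 1).all() for p in planes.values())

    def test_value_five_sets_bits_zero_and_two(self):
        frame = np.zeros((2, 2, 3), np.uint8)
        frame[0, 1, 1] = 5  # 00000101 in green
        planes = vio.decompose_bitplanes(frame)
        for b in range(8):
            expected = 1 if b in (0, 2) else 0
            assert planes[("G", b)][0, 1] == expected
        assert all((planes[(c, b)] == 0).all() for c in "RB" for b in range(8))

    def test_roundtrip_all_256_values(self):
        # every possible channel value, exhaustively
        vals = np.arange(256, dtype=np.uint8).reshape(16, 16)
        frame = np.stack([vals, vals[::-1], vals.T], axis=-1)
        planes = vio.decompose_bitplanes(frame)
        for ci, c in enumerate("RGB"):
            rec = vio.reconstruct_channel([planes[(c, b)] for b in range(8)])
            np.testing.assert_array_equal(rec, frame[..., ci])

    def test_roundtrip_random_frames(self, rng):
        for _ in range(10):
            frame = rng.integers(0, 256, size=(8, 9, 3), dtype=np.uint8)
            planes = vio.decompose_bitplanes(frame)
            assert all(set(np.unique(p)) <= {0, 1} for p in planes.values())
            for ci, c in enumerate("RGB"):
                rec = vio.reconstruct_channel([planes[(c, b)] for b in range(8)])
                np.testing.assert_array_equal(rec, frame[..., ci])

    def test_msb_plane_alone_reconstructs_128(self):
        planes = [np.zeros((3, 3), np.uint8) for _ in range(8)]
        planes[7] = np.ones((3, 3), np.uint8)
        np.testing.assert_array_equal(vio.reconstruct_channel(planes),
                                      np.full((3, 3), 128, np.uint8))

    @pytest.mark.parametrize("bad", [
        np.zeros((4, 5), np.uint8),              # not 3-channel
        np.zeros((4, 5, 3), np.float32),         # not integer
        np.full((4, 5, 3), 300, np.int32),       # out of 8-bit range
    ])
    def test_format_errors(self, bad):
        with pytest.raises(ValueError):
            vio.decompose_bitplanes(bad)

    def test_wrong_plane_count_rejected(self):
        with pytest.raises(ValueError):
            vio.reconstruct_channel([np.zeros((2, 2), np.uint8)] * 7)


class TestAverageRoi:
    def test_uniform_frame(self):
        video = np.full((5, 4, 4), 7.0)
        roi = np.zeros((4, 4), bool)
        roi[1:3, 1:3] = True
        np.testing.assert_allclose(vio.average_roi(video, roi), 7.0)

    def test_two_pixel_mean(self):
        video = np.zeros((1, 2, 2))
        video[0, 0, 0], video[0, 0, 1] = 4.0, 10.0
        roi = np.zeros((2, 2), bool)
        roi[0, :] = True
        np.testing.assert_allclose(vio.average_roi(video, roi), [7.0])

    def test_checkerboard_matches_pixel_loop(self):
        yy, xx = np.mgrid[0:6, 0:6]
        frame = ((yy + xx) % 2).astype(float)
        video = frame[None]
        roi = np.ones((6, 6), bool)
        # independent brute-force oracle: explicit pixel loop
        acc = sum(frame[y, x] for y in range(6) for x in range(6) if roi[y, x])
        expected = acc / roi.sum()
        assert expected == 0.5
        np.testing.assert_allclose(vio.average_roi(video, roi), [expected])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            vio.average_roi(np.zeros((2, 3, 3)), np.zeros((3, 3), bool))

    @settings(derandomize=True, max_examples=25)
    @given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5), seed=st.integers(0, 999))
    def test_linearity(self, alpha, beta, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 4, 5, 5))
        roi = np.zeros((5, 5), bool)
        roi[r.integers(0, 5), r.integers(0, 5)] = True
        roi[0, 0] = True
        lhs = vio.average_roi(alpha * x + beta * y, roi)
        rhs = alpha * vio.average_roi(x, roi) + beta * vio.average_roi(y, roi)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestRoiConfigAndVideoIO:
    def test_rect_config_half_open(self):
        cfg = {"frame_shape": [8, 10],
               "rois": {"Forehead Small": {"type": "rect", "x0": 2, "y0": 1,
                                           "x1": 5, "y1": 3}}}
        roi_map = vio.roi_map_from_config(cfg)
        mask = roi_map["Forehead Small"]
        assert mask.sum() == (5 - 2) * (3 - 1)
        assert mask[1, 2] and mask[2, 4]
        assert not mask[3, 2] and not mask[1, 5]

    def test_config_roundtrip(self, tmp_path):
        cfg = {"frame_shape": [8, 8],
               "rois": {"Chin Small": {"type": "rect", "x0": 0, "y0": 4,
                                       "x1": 3, "y1": 8}}}
        path = tmp_path / "rois.json"
        path.write_text(json.dumps(cfg))
        roi_map = vio.roi_map_from_config(path)
        back = vio.roi_map_to_config(roi_map)
        assert back["rois"]["Chin Small"] == cfg["rois"]["Chin Small"]

    def test_out_of_bounds_rect_rejected(self):
        cfg = {"frame_shape": [4, 4],
               "rois": {"Upper Lip": {"type": "rect", "x0": 0, "y0": 0,
                                      "x1": 5, "y1": 2}}}
        with pytest.raises(ValueError):
            vio.roi_map_from_config(cfg)

    def test_npz_roundtrip_is_bit_exact(self, tmp_path, rng):
        frames = rng.integers(0, 256, size=(12, 6, 7, 3), dtype=np.uint8)
        stack = vio.FrameStack(frames=frames, fps=60.0)
        path = tmp_path / "clip.npz"
        vio.write_video(path, stack)
        loaded = vio.read_video(path)
        assert loaded.fps == 60.0
        np.testing.assert_array_equal(loaded.frames, frames)

    def test_roi_bitplane_means_match_direct_average(self, rng):
        frames = rng.integers(0, 256, size=(20, 8, 8, 3), dtype=np.uint8)
        stack = vio.FrameStack(frames=frames, fps=60.0)
        mask = np.zeros((8, 8), bool)
        mask[2:6, 3:7] = True
        roi_map = vio.ROIMap(rois={"Nose Tip Small": mask})
        rows = vio.roi_bitplane_means(stack, roi_map)["Nose Tip Small"]
        planes_t0 = vio.decompose_bitplanes(frames[0])
        for c in "RGB":
            for b in range(8):
                i = vio.plane_index(c, b)
                assert rows[i, 0] == pytest.approx(planes_t0[(c, b)][mask].mean())
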