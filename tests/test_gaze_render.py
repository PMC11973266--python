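"""Gaze-contingent rendering: the Canny baseline, aperture geometry and
session replay."""

import numpy as np
import pytest

from pointspv.encoder import EncoderConfig, init_encoder
from pointspv.gaze_render import (RenderConfig, ScreenFrame,
                                  canny_representation, render_frame,
                                  simulate_session)
from pointspv.simulator import SimulatorConfig
from pointspv.synthetic import SyntheticGazeLog, GazeSample


@pytest.fixture(scope="module")
def small_cfg():
    """A 200x200 'screen' with a 64-frame simulator and 25 px aperture."""
    return RenderConfig(screen_size=(200, 200), patch_size=50, aperture_radius=25,
                        method="canny",
                        sim_config=SimulatorConfig(frame_size=64, grid_size=8))


@pytest.fixture(scope="module")
def screen_image(small_cfg):
    rng = np.random.default_rng(0)
    return rng.random((200, 200, 3))


class TestCannyRepresentation:
    def test_constant_patch_gives_zero_frame(self, small_cfg):
        frame = canny_representation(np.full((50, 50, 3), 0.5), small_cfg)
        assert frame.pixels.shape == (64, 64)
        assert not frame.pixels.any()

    def test_vertical_step_edge_activates_single_grid_column(self, small_cfg):
        # boundary placed mid-cell so the edge stays in one grid column
        patch = np.full((64, 64, 3), 0.1)
        patch[:, 28:] = 0.9
        frame = canny_representation(patch, small_cfg)
        g = small_cfg.sim_config.grid_size
        s = small_cfg.sim_config.spacing
        active_cols = {c for r in range(g) for c in range(g)
                       if frame.pixels[r * s:(r + 1) * s, c * s:(c + 1) * s].any()}
        assert len(active_cols) == 1

    def test_through_simulator_matches_pointspv_frame_size(self, small_cfg):
        patch = np.random.default_rng(1).random((50, 50, 3))
        frame = canny_representation(patch, small_cfg)
        assert frame.pixels.shape == (small_cfg.sim_config.frame_size,) * 2

    def test_raw_edges_mode(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, canny_mode="raw_edges")
        patch = np.random.default_rng(1).random((50, 50, 3))
        frame = canny_representation(patch, cfg)
        assert frame.pixels.shape == (64, 64)
        assert frame.pixels.min() >= 0 and frame.pixels.max() <= 1

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RenderConfig(canny_low=200, canny_high=100)


class TestRenderFrame:
    def test_aperture_containment_center_gaze(self, screen_image, small_cfg):
        frame = render_frame(screen_image, (100, 100), None, small_cfg)
        yy, xx = np.mgrid[0:200, 0:200]
        outside = (yy - 100) ** 2 + (xx - 100) ** 2 > 25 ** 2
        assert not frame.pixels[outside].any()

    def test_disk_pixel_count_brute_force(self, screen_image, small_cfg):
        """The allowed region is exactly {p : dist(p, gaze) <= r}, checked
        by brute-force disk rasterization."""
        gy, gx, r = 80, 120, small_cfg.radius
        frame = render_frame(screen_image, (gy, gx), None, small_cfg)
        allowed = set()
        for y in range(200):
            for x in range(200):
                if (y - gy) ** 2 + (x - gx) ** 2 <= r ** 2:
                    allowed.add((y, x))
        for y, x in zip(*np.nonzero(frame.pixels)):
            assert (y, x) in allowed
        # oracle count for an interior disk: matches the quadrance formula
        assert len(allowed) == sum((dy * dy + dx * dx <= r * r)
                                   for dy in range(-r, r + 1)
                                   for dx in range(-r, r + 1))

    def test_two_gaze_points_differ_only_in_placement(self, screen_image, small_cfg):
        f1 = render_frame(screen_image, (60, 60), None, small_cfg)
        f2 = render_frame(screen_image, (140, 140), None, small_cfg)
        assert f1.pixels.shape == f2.pixels.shape
        assert f1.gaze != f2.gaze
        # each respects its own aperture
        for f in (f1, f2):
            yy, xx = np.mgrid[0:200, 0:200]
            outside = (yy - f.gaze[0]) ** 2 + (xx - f.gaze[1]) ** 2 > 25 ** 2
            assert not f.pixels[outside].any()

    def test_gaze_off_screen_rejected(self, screen_image, small_cfg):
        with pytest.raises(ValueError):
            render_frame(screen_image, (250, 100), None, small_cfg)

    def test_pointspv_and_canny_share_geometry(self, screen_image, small_cfg):
        import dataclasses
        enc = init_encoder(EncoderConfig(patch_size=50, internal_size=64,
                                         grid_size=8), rng_seed=0)
        cfg_p = dataclasses.replace(small_cfg, method="pointspv")
        fp = render_frame(screen_image, (100, 100), enc, cfg_p)
        fc = render_frame(screen_image, (100, 100), None, small_cfg)
        assert fp.pixels.shape == fc.pixels.shape
        assert fp.method == "pointspv" and fc.method == "canny"

    def test_pointspv_requires_encoder(self, screen_image, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, method="pointspv")
        with pytest.raises(ValueError):
            render_frame(screen_image, (100, 100), None, cfg)


class TestSimulateSession:
    def make_log(self, n=5):
        samples = []
        t = 0.0
        rng = np.random.default_rng(3)
        for _ in range(n):
            y, x = rng.uniform(30, 170, size=2)
            t += 30
            samples.append(GazeSample(t_ms=t, x=x, y=y, event="saccade"))
            t += 200
            samples.append(GazeSample(t_ms=t, x=x, y=y, event="fixation"))
        return SyntheticGazeLog(trial_id="t", samples=samples, response_t=t + 100)

    def test_one_frame_per_sample_in_time_order(self, screen_image, small_cfg):
        log = self.make_log(5)
        frames = simulate_session(screen_image, log, None, small_cfg)
        assert len(frames) == 10  # 5 fixations + 5 saccades
        gazes = [(int(round(s.y)), int(round(s.x)))
                 for s in sorted(log.samples, key=lambda s: s.t_ms)]
        assert [f.gaze for f in frames] == gazes

    def test_replay_bit_identical(self, screen_image, small_cfg):
        log = self.make_log(3)
        a = simulate_session(screen_image, log, None, small_cfg)
        b = simulate_session(screen_image, log, None, small_cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)

    def test_every_frame_respects_aperture(self, screen_image, small_cfg):
        log = self.make_log(4)
        yy, xx = np.mgrid[0:200, 0:200]
        for f in simulate_session(screen_image, log, None, small_cfg):
            outside = (yy - f.gaze[0]) ** 2 + (xx - f.gaze[1]) ** 2 > 25 ** 2
            assert not f.pixels[outside].any()

    def test_blank_saccades_flag(self, screen_image, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, blank_saccades=True)
        log = self.make_log(3)
        frames = simulate_session(screen_image, log, None, cfg)
        for f, s in zip(frames, sorted(log.samples, key=lambda s: s.t_ms)):
            if s.event == "saccade":
                assert not f.pixels.any()

    def test_empty_log_empty_list(self, screen_image, small_cfg):
        log = SyntheticGazeLog(trial_id="t", samples=[], response_t=0.0)
        assert simulate_session(screen_image, log, None, small_cfg) == []
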