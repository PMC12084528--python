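"""Synthetic video generator and the closed-form design calculators."""

import numpy as np
import pandas as pd
import pytest

from dropcode.simulate import (ChannelGeometry, ExcitationSchedule, GroupSpec,
                               NoiseModel, PopulationModel, design_velocity,
                               expected_positive_spacing, make_backgrounds,
                               render_video, sample_beads, simulate_run,
                               streak_length)
from dropcode.mls import default_codes


class TestDesignCalculators:
    def test_positive_spacing_one_percent(self):
        # 1% positives of 80-um droplets sit 100 diameters = 8 mm apart
        assert expected_positive_spacing(0.01, 80.0) == pytest.approx(8000.0)

    def test_positive_spacing_all_positive(self):
        assert expected_positive_spacing(1.0, 80.0) == pytest.approx(80.0)

    def test_positive_spacing_invalid_fraction(self):
        with pytest.raises(ValueError):
            expected_positive_spacing(0.0, 80.0)

    def test_positive_spacing_matches_bernoulli_train(self):
        # mean nearest-successor spacing of a simulated droplet train
        rng = np.random.default_rng(42)
        n, p, d = 100_000, 0.01, 80.0
        positives = np.flatnonzero(rng.random(n) < p)
        gaps = np.diff(positives) * d
        expected = expected_positive_spacing(p, d)
        se = gaps.std(ddof=1) / np.sqrt(gaps.size)
        assert abs(gaps.mean() - expected) < 4 * se

    def test_bead_streak_is_third_of_channel(self):
        v = design_velocity()  # 23 mm channel, T1 = 41.5 ms
        assert streak_length(v, 41.5) == pytest.approx(23000.0 / 3)

    def test_substrate_streak_about_2mm(self):
        v = design_velocity()
        assert streak_length(v, 10.0) == pytest.approx(1847.4, abs=1.0)

    def test_zero_velocity_zero_streak(self):
        assert streak_length(0.0, 10.0) == 0.0


class TestGeometry:
    def test_default_channel_count_fits_frame(self):
        g = ChannelGeometry()
        assert g.n_channels == 76
        assert g.n_channels * g.pitch_px <= g.frame_shape[0]

    def test_channel_rows_disjoint(self):
        g = ChannelGeometry()
        rows = [g.channel_rows(n) for n in range(g.n_channels)]
        stops = [r.stop for r in rows]
        starts = [r.start for r in rows]
        assert all(a < b for a, b in zip(stops, starts[1:]))

    def test_band_overflow_rejected(self):
        with pytest.raises(ValueError):
            ChannelGeometry(n_channels=800)


class TestSampleBeads:
    def test_zero_cv_gives_identical_intensities(self):
        model = PopulationModel(groups={"A": GroupSpec(1.0, 2.0, 0.0, 0.0)})
        truth = sample_beads(model, 50, seed=1)
        assert np.allclose(truth.b1, 1.0)
        assert np.allclose(truth.b2, 2.0)

    def test_positive_count_binomial(self):
        model = PopulationModel(hrp_positive_fraction=0.01)
        truth = sample_beads(model, 10_000, seed=2)
        n, p = 10_000, 0.01
        sd = np.sqrt(n * p * (1 - p))
        assert abs(truth.hrp_positive.sum() - n * p) <= 3 * sd

    def test_group_mean_recovery(self):
        model = PopulationModel()
        truth = sample_beads(model, 3000, seed=3)
        for lab, spec in model.groups.items():
            grp = truth[truth.group == lab]
            for col, mean, cv in [("b1", spec.mean_b1, spec.cv1),
                                  ("b2", spec.mean_b2, spec.cv2)]:
                se = cv * mean / np.sqrt(len(grp))
                assert abs(grp[col].mean() - mean) < 3 * se

    def test_empirical_cv_near_configured(self):
        model = PopulationModel()
        truth = sample_beads(model, 3000, seed=4)
        for lab, spec in model.groups.items():
            grp = truth[truth.group == lab]
            cv = grp.b1.std(ddof=1) / grp.b1.mean()
            assert cv == pytest.approx(spec.cv1, rel=0.20)

    def test_deterministic_per_seed(self):
        model = PopulationModel()
        a = sample_beads(model, 200, seed=5)
        b = sample_beads(model, 200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_empty_inputs(self):
        with pytest.raises(ValueError):
            PopulationModel(groups={})
        with pytest.raises(ValueError):
            sample_beads(PopulationModel(), 0, seed=0)


@pytest.fixture(scope="module")
def tiny_setup():
    geometry = ChannelGeometry()
    schedule = ExcitationSchedule()
    model = PopulationModel()
    codes = default_codes()
    background = make_backgrounds(geometry, model, seed=0)
    return geometry, schedule, model, codes, background


class TestRenderVideo:
    def test_zero_beads_is_background(self, tiny_setup):
        geometry, schedule, model, codes, background = tiny_setup
        truth = pd.DataFrame(columns=["bead_id", "group", "channel", "frame",
                                      "x0_px", "velocity", "v_px", "b1",
                                      "b2", "hrp_positive", "edge"])
        stack = render_video(geometry, schedule, codes, truth, background,
                             n_frames=2, noise=None)
        assert np.array_equal(
            stack.frames[0],
            np.clip(np.round(background["bead"]), 0, 65535).astype(np.uint16))

    def test_one_bead_photon_budget(self, tiny_setup):
        # noiseless: the normalized excess signal integrated over the
        # bead's channel equals (b1*duty*sum(mask1) + b2*sum(mask2)) * width
        geometry, schedule, model, codes, background = tiny_setup
        from dropcode.mls import render_mask
        v_px = 7.5
        truth = pd.DataFrame([{
            "bead_id": 0, "group": "C", "channel": 10, "frame": 0,
            "x0_px": 50.0, "velocity": v_px * geometry.pixel_scale,
            "v_px": v_px, "b1": 1.2, "b2": 0.7, "hrp_positive": False,
            "edge": False,
        }])
        stack = render_video(geometry, schedule, codes, truth, background,
                             n_frames=1, noise=None)
        norm = stack.frames[0].astype(float) / background["bead"]
        excess = (norm - 1.0)[geometry.channel_rows(10)].sum()
        m1 = render_mask(codes[0], v_px, schedule.t1)
        m2 = render_mask(codes[1], v_px, schedule.t1)
        expected = (1.2 * schedule.blue_duty * m1.sum() + 0.7 * m2.sum()) \
            * geometry.channel_width_px
        # 16-bit quantisation of counts adds <1 count/pixel of rounding
        assert excess == pytest.approx(expected, rel=0.01)

    def test_substrate_streak_quarter_of_bead_streak(self, tiny_setup):
        # the substrate exposure is a quarter of the bead exposure, so a
        # positive droplet's substrate streak is ~1/4 of its MLS streak
        geometry, schedule, model, codes, background = tiny_setup
        v_px = 7.7
        truth = pd.DataFrame([{
            "bead_id": 0, "group": "C", "channel": 5, "frame": 0,
            "x0_px": 20.0, "velocity": v_px * geometry.pixel_scale,
            "v_px": v_px, "b1": 1.0, "b2": 1.0, "hrp_positive": True,
            "edge": False,
        }])
        stack = render_video(geometry, schedule, codes, truth, background,
                             n_frames=2, noise=None)
        rows = geometry.channel_rows(5)
        bead_trace = (stack.frames[0].astype(float)
                      / background["bead"])[rows].mean(axis=0)
        sub_trace = (stack.frames[1].astype(float)
                     / background["substrate"])[rows].mean(axis=0)
        bead_len = np.count_nonzero(bead_trace > 1.05)
        # MLS zeros leave gaps: measure the occupied span instead
        on = np.flatnonzero(bead_trace > 1.05)
        bead_span = on[-1] - on[0] + 1 if on.size else 0
        sub_len = np.count_nonzero(sub_trace > 1.05)
        assert bead_len > 0 and sub_len > 0
        assert sub_len / bead_span == pytest.approx(
            schedule.t2 / schedule.t1, rel=0.10)

    def test_hrp_negative_leaves_substrate_frame_clean(self, tiny_setup):
        geometry, schedule, model, codes, background = tiny_setup
        truth = sample_beads(
            PopulationModel(hrp_positive_fraction=0.0), 20, seed=9)
        stack = render_video(geometry, schedule, codes, truth, background,
                             noise=None)
        for m in stack.frame_indices("substrate"):
            expected = np.clip(np.round(background["substrate"]), 0,
                               65535).astype(np.uint16)
            assert np.array_equal(stack.frames[m], expected)

    def test_photon_conservation(self, tiny_setup):
        # noiseless, unclipped: total excess counts equal the sum of the
        # per-bead closed-form contributions
        geometry, schedule, model, codes, background = tiny_setup
        from dropcode.mls import render_mask
        truth = sample_beads(PopulationModel(hrp_positive_fraction=0.0),
                             10, seed=11)
        stack = render_video(geometry, schedule, codes, truth, background,
                             noise=None)
        m = 0
        frame_truth = stack.truth[stack.truth.frame == 0]
        norm = stack.frames[m].astype(float) / background["bead"]
        total_excess = (norm - 1.0).sum()
        expected = 0.0
        for bead in frame_truth.itertuples():
            m1 = render_mask(codes[0], bead.v_px, schedule.t1)
            m2 = render_mask(codes[1], bead.v_px, schedule.t1)
            expected += (bead.b1 * schedule.blue_duty * m1.sum()
                         + bead.b2 * m2.sum()) * geometry.channel_width_px
        assert total_excess == pytest.approx(expected, rel=0.02)

    def test_bit_identical_reruns(self):
        model = PopulationModel()
        a, _, _ = simulate_run(model, 30, seed=17)
        b, _, _ = simulate_run(model, 30, seed=17)
        assert np.array_equal(a.frames, b.frames)

    def test_pixels_are_16bit(self):
        model = PopulationModel(noise=NoiseModel(shot=True, read_sd=50.0))
        stack, _, _ = simulate_run(model, 20, seed=8)
        assert stack.frames.dtype == np.uint16


class TestSaveLoad:
    def test_stack_roundtrip(self, tmp_path):
        model = PopulationModel()
        stack, _, truth = simulate_run(model, 10, seed=19)
        stack.save(tmp_path)
        loaded = type(stack).load(tmp_path)
        assert np.array_equal(loaded.frames, stack.frames)
        assert loaded.roles == stack.roles
        assert len(loaded.truth) == len(truth)
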