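"""Profile extraction and column-width measurement against closed forms."""

import numpy as np
import pytest

from hvipipe.exceptions import (MeasurementFailure, ParameterError,
                                UnmeasurableProfileError)
from hvipipe.synthetic import render_video
from hvipipe.width import (IntensityProfile, SamplingLine, WidthMeasurement,
                           average_observers, extract_profile, measure_width,
                           measure_width_clip, percent_change)

from conftest import scene_for_width, vertical_line_through_axis


def cosine_double_well(n=65, centers=(12.0, 52.0), half_width=6.0,
                       plateau=0.8, floor=0.15):
    """Closed-form profile with local minima exactly at ``centers``: each
    well is an even raised-cosine dip, the rest is a flat plateau."""
    x = np.arange(n, dtype=np.float64)
    y = np.full(n, plateau)
    for c in centers:
        u = np.abs(x - c)
        m = u <= half_width
        y[m] = floor + (plateau - floor) * np.sin(np.pi * u[m] /
                                                  (2 * half_width)) ** 2
    return IntensityProfile(positions=x, intensities=y)


class TestExtractProfile:
    def test_constant_frame_gives_constant_profile(self):
        frame = np.full((20, 30), 0.3)
        prof = extract_profile(frame, SamplingLine(2, 3, 27, 15))
        np.testing.assert_allclose(prof.intensities, 0.3)

    def test_dark_stripe_minimum_located(self):
        frame = np.full((16, 40), 0.8)
        frame[:, 22] = 0.1  # vertical dark stripe
        prof = extract_profile(frame, SamplingLine(0, 8, 39, 8))
        assert abs(prof.positions[np.argmin(prof.intensities)] - 22) <= 0.5

    def test_axis_aligned_line_reproduces_pixels(self):
        rng = np.random.default_rng(2)
        frame = rng.random((10, 25))
        prof = extract_profile(frame, SamplingLine(0, 4, 24, 4))
        np.testing.assert_allclose(prof.intensities, frame[4, :], atol=1e-12)

    def test_line_outside_frame_rejected(self):
        with pytest.raises(ParameterError):
            extract_profile(np.zeros((10, 10)), SamplingLine(0, 0, 15, 0))

    def test_degenerate_line_rejected(self):
        with pytest.raises(ParameterError):
            SamplingLine(3, 3, 3, 3)


class TestMeasureWidth:
    def test_closed_form_double_well(self):
        prof = cosine_double_well()
        assert measure_width(prof) == pytest.approx(40.0, abs=0.1)

    def test_noiseless_render_recovers_forty_pixels(self):
        params = scene_for_width(40.0, noise_sd=0.0, speckle_contrast=0.0,
                                 n_frames=1, seed=9)
        clip, _ = render_video(params)
        prof = extract_profile(clip.frames[0],
                               vertical_line_through_axis(params))
        assert measure_width(prof) == pytest.approx(40.0, abs=0.5)

    def test_monotone_ramp_unmeasurable(self):
        prof = IntensityProfile(positions=np.arange(50.0),
                                intensities=np.linspace(0.1, 0.9, 50))
        with pytest.raises(UnmeasurableProfileError):
            measure_width(prof)

    def test_single_well_unmeasurable(self):
        x = np.arange(60.0)
        y = 0.8 - 0.6 * np.exp(-0.5 * ((x - 30) / 4) ** 2)
        with pytest.raises(UnmeasurableProfileError):
            measure_width(IntensityProfile(positions=x, intensities=y))

    def test_translation_invariance(self):
        """Shifting frame and line together leaves the width unchanged."""
        params = scene_for_width(40.0, noise_sd=0.02, n_frames=1, seed=10)
        clip, _ = render_video(params)
        frame = clip.frames[0]
        base_line = vertical_line_through_axis(params)
        w0 = measure_width(extract_profile(frame, base_line))
        for dx in (-7, 5):
            shifted = np.roll(frame, dx, axis=1)
            line = SamplingLine(base_line.x0 + dx, base_line.y0,
                                base_line.x1 + dx, base_line.y1)
            w1 = measure_width(extract_profile(shifted, line))
            assert w1 == pytest.approx(w0, abs=0.1)


class TestMeasureWidthClip:
    def test_static_noiseless_clip_zero_sd(self):
        params = scene_for_width(40.0, noise_sd=0.0, speckle_contrast=0.0,
                                 flow_speed_px_per_frame=0.0, n_frames=30,
                                 seed=11)
        clip, _ = render_video(params)
        m = measure_width_clip(clip, vertical_line_through_axis(params))
        assert np.ptp(m.per_frame_widths) == 0.0
        assert m.sd_width_px == pytest.approx(0.0, abs=1e-9)
        assert m.n_unmeasurable == 0

    def test_noisy_clip_mean_within_one_pixel(self):
        params = scene_for_width(40.0, noise_sd=0.03, n_frames=30, seed=12)
        clip, _ = render_video(params)
        m = measure_width_clip(clip, vertical_line_through_axis(params))
        assert m.mean_width_px == pytest.approx(40.0, abs=1.0)

    def test_short_clip_rejected(self):
        params = scene_for_width(40.0, n_frames=10, seed=13)
        clip, _ = render_video(params)
        with pytest.raises(ParameterError):
            measure_width_clip(clip, vertical_line_through_axis(params),
                               n_frames=30)

    def test_unmeasurable_majority_fails(self):
        from hvipipe.video_io import VideoClip
        clip = VideoClip(np.full((30, 20, 20), 0.5), fps=30)
        with pytest.raises(MeasurementFailure):
            measure_width_clip(clip, SamplingLine(1, 10, 18, 10))


class TestObserverAveragingAndPercentChange:
    @staticmethod
    def measurement(mean):
        return WidthMeasurement(per_frame_widths=np.array([mean]),
                                mean_width_px=mean, sd_width_px=0.0)

    def test_average_of_two_observers(self):
        assert average_observers(self.measurement(80.0),
                                 self.measurement(82.0)) == 81.0
        assert average_observers(self.measurement(64.0),
                                 self.measurement(64.0)) == 64.0

    def test_offset_line_placements_average_near_truth(self):
        """Two observers with lines offset ±2 px along the vessel still
        recover the width: the scene is uniform along its axis."""
        params = scene_for_width(40.0, noise_sd=0.02, n_frames=30, seed=14)
        clip, _ = render_video(params)
        base = vertical_line_through_axis(params)
        m1 = measure_width_clip(clip, SamplingLine(base.x0 - 2, base.y0,
                                                   base.x1 - 2, base.y1),
                                observer_label="MS")
        m2 = measure_width_clip(clip, SamplingLine(base.x0 + 2, base.y0,
                                                   base.x1 + 2, base.y1),
                                observer_label="YS")
        assert average_observers(m1, m2) == pytest.approx(40.0, abs=1.0)

    def test_percent_change_arithmetic(self):
        assert percent_change(50.0, 50.0) == 0.0
        assert percent_change(50.0, 75.0) == 50.0
        # percent change of the group means differs from the mean of
        # per-subject percent changes; this is the former
        assert percent_change(63.7, 81.2) == pytest.approx(27.47, abs=0.01)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ParameterError):
            percent_change(0.0, 10.0)
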