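import numpy as np
import pytest

from hvipipe.synthetic import SceneParams, render_video


def scene_for_width(column_width_px: float, **overrides) -> SceneParams:
    """A scene sized so the vessel fits comfortably, vertical measurement
    line friendly (horizontal axis unless overridden)."""
    vessel = max(2.2 * column_width_px, column_width_px + 15.0)
    h = int(vessel + 40)
    w = h + 20
    defaults = dict(column_width_px=column_width_px, vessel_width_px=vessel,
                    image_height_px=h, image_width_px=w,
                    axis_point=(w / 2, h / 2), axis_angle_deg=0.0,
                    jitter_sd_px=0.0)
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture(scope="session")
def quiet_clip():
    """A small noiseless, jitter-free, speckle-free rendered clip."""
    params = scene_for_width(40.0, noise_sd=0.0, speckle_contrast=0.0,
                             background_texture_contrast=0.0, n_frames=5, seed=1)
    clip, truth = render_video(params)
    return params, clip, truth


@pytest.fixture(scope="session")
def textured_frame():
    """One frame with texture everywhere (for registration tests)."""
    params = SceneParams(noise_sd=0.0, jitter_sd_px=0.0, n_frames=2, seed=11)
    clip, _ = render_video(params)
    return clip.frames[0]


def vertical_line_through_axis(params: SceneParams):
    from hvipipe.width import SamplingLine
    x = params.axis_point[0]
    return SamplingLine(x, 2.0, x, params.image_height_px - 3.0)


def assert_all_finite(arr):
    assert np.isfinite(np.asarray(arr)).all()
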