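"""Shared fixtures: synthetic sessions and frames, generated at test time."""

import numpy as np
import pytest

from biopsyguide import phantom as ph
from biopsyguide.riskmap import WidefieldFrame
from biopsyguide.scoring import MicroFrame


@pytest.fixture(scope="session")
def default_session():
    """Full default phantom session (seed 7); shared by end-to-end tests."""
    return ph.generate_session(ph.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_session():
    """Short, low-rate session for fast plumbing tests."""
    spec = ph.PhantomSpec(
        seed=3,
        duration_s=1.0,
        rates=ph.RateSpec(widefield_fps=10.0, micro_fps=30.0),
        # short trajectory that still crosses the lesion edge within 1 s
        trajectory=ph.TrajectorySpec(waypoints=((430.0, 300.0), (700.0, 300.0))),
    )
    return ph.generate_session(spec)


@pytest.fixture(scope="session")
def normal_micro_frame():
    frame, nuclei = ph.generate_micro_frame(ph.PhantomSpec(seed=11), "normal", 0)
    return frame, nuclei


@pytest.fixture(scope="session")
def dysplastic_micro_frame():
    frame, nuclei = ph.generate_micro_frame(ph.PhantomSpec(seed=11), "dysplastic", 1000)
    return frame, nuclei


def make_marker_frame(width, height, x, y, radius=6.0, hue_deg=180.0, frame_index=0,
                      timestamp=0.0):
    """Small widefield frame with a colored marker disc on a dark background."""
    from skimage.color import hsv2rgb

    img = np.full((height, width, 3), 40.0)
    rgb = hsv2rgb(np.array([[[hue_deg / 360.0, 0.85, 0.9]]]))[0, 0] * 255.0
    ys, xs = np.ogrid[:height, :width]
    disc = (xs - x) ** 2 + (ys - y) ** 2 <= radius**2
    img[disc] = rgb
    return WidefieldFrame(pixels=img, timestamp=timestamp, modality="WL",
                          frame_index=frame_index)


def make_micro_from_array(pixels, fov_radius=None, **kwargs):
    h, w = pixels.shape
    r = fov_radius if fov_radius is not None else 0.45 * min(h, w)
    return MicroFrame(pixels=pixels, fov_center=(w / 2, h / 2), fov_radius=r, **kwargs)
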