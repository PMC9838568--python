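"""Microendoscopy mosaicking and score-versus-distance profiles.

Consecutive frames acquired at 90 fps overlap heavily, so translation is
the dominant inter-frame motion and pairwise phase correlation suffices to
register them. Global placements are obtained by chaining pairwise offsets;
links whose normalized correlation peak falls below a floor are flagged and
the chain resumes from the last trusted placement rather than discarding
data. Frames are composited with feathered (distance-to-field-edge
weighted) averaging, extending the effective field of view of the probe.

The score profile summarizes diagnosis along the imaging path: cumulative
arc length is measured along the smoothed probe track, each scored micro
frame inherits the arc length of its associated widefield frame, and scores
are averaged in consecutive distance bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .exceptions import InputError
from .fusion import StreamAssociation
from .geometry import CalibrationModel, pixels_to_mm
from .scoring import DEFAULT_UM_PER_PX, FrameScore, MicroFrame, fov_mask
from .tracking import ProbeTrack

__all__ = [
    "FramePlacement",
    "MosaicCanvas",
    "ScoreProfile",
    "register_pair",
    "build_mosaic",
    "score_profile",
]

DEFAULT_MIN_PEAK = 0.2
DEFAULT_BIN_WIDTH_MM = 0.5


def _parabolic_refine(r: np.ndarray, peak_idx: tuple[int, int]) -> tuple[float, float]:
    """Subpixel refinement of a correlation peak by 1-D parabola fits per axis."""
    out = []
    for axis, idx in enumerate(peak_idx):
        n = r.shape[axis]
        sel = list(peak_idx)
        sel[axis] = (idx - 1) % n
        ym = r[tuple(sel)]
        sel[axis] = idx
        y0 = r[tuple(sel)]
        sel[axis] = (idx + 1) % n
        yp = r[tuple(sel)]
        denom = ym - 2 * y0 + yp
        delta = 0.5 * (ym - yp) / denom if abs(denom) > 1e-12 else 0.0
        out.append(idx + float(np.clip(delta, -0.5, 0.5)))
    return out[0], out[1]


def register_pair(a: MicroFrame, b: MicroFrame) -> tuple[float, float, float]:
    """Translation of image content from ``a`` to ``b`` by phase correlation.

    Returns ``(dx, dy, correlation_peak)`` such that
    ``b(x, y) ~ a(x - dx, y - dy)``. Pixels outside the circular field of
    view are replaced by the in-field mean before the FFT; the integer peak
    of the normalized cross-power spectrum is refined to subpixel precision
    by a parabolic fit, and ``correlation_peak`` is the normalized peak
    height (1 for a perfect circular shift). A low peak is reported, never
    raised.
    """
    if a.shape != b.shape:
        raise InputError("frames must share dimensions")
    fov = fov_mask(a)

    def prep(frame: MicroFrame) -> np.ndarray:
        img = frame.pixels.astype(np.float64)
        mean = img[fov].mean()
        img[~fov] = mean
        return img - mean

    fa = np.fft.fft2(prep(a))
    fb = np.fft.fft2(prep(b))
    cross = fb * np.conj(fa)
    cross /= np.abs(cross) + 1e-12
    r = np.real(np.fft.ifft2(cross))
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    peak = float(r[iy, ix])
    ry, rx = _parabolic_refine(r, (iy, ix))
    h, w = r.shape
    dy = ry if ry <= h / 2 else ry - h
    dx = rx if rx <= w / 2 else rx - w
    return float(dx), float(dy), peak


@dataclass(frozen=True)
class FramePlacement:
    frame_index: int
    offset: tuple[float, float]  # global (dx, dy) of the frame origin, px
    correlation_peak: float
    chained_valid: bool


@dataclass
class MosaicCanvas:
    image: np.ndarray
    weight: np.ndarray
    placements: list[FramePlacement]
    um_per_px: float

    @property
    def physical_width_um(self) -> float:
        """Mosaic x-extent in px times the pixel pitch."""
        return self.image.shape[1] * self.um_per_px


def _feather_weight(frame: MicroFrame) -> np.ndarray:
    """Per-pixel blend weight: distance to the field-of-view edge."""
    fov = fov_mask(frame)
    return ndi.distance_transform_edt(fov)


def build_mosaic(
    frames: list[MicroFrame],
    scores: list[FrameScore] | None = None,
    min_peak: float = DEFAULT_MIN_PEAK,
    um_per_px: float = DEFAULT_UM_PER_PX,
) -> MosaicCanvas:
    """Composite a frame sequence into a mosaic by chained registration.

    Pairwise offsets are chained into global placements; a link whose
    correlation peak falls below ``min_peak`` marks the frame (and the chain
    from it) ``chained_valid=False`` and keeps the last trusted offset, so
    the data is preserved but its geometry is flagged. Compositing is a
    feathered average weighted by distance to the field-of-view edge.
    """
    if len(frames) == 0:
        raise InputError("build_mosaic needs at least one frame")
    del scores  # placements are geometric; scores travel with the profile

    offsets = [(0.0, 0.0)]
    placements = [FramePlacement(frames[0].frame_index, (0.0, 0.0), 1.0, True)]
    for prev, cur in zip(frames, frames[1:]):
        dx, dy, peak = register_pair(prev, cur)
        ox, oy = offsets[-1]
        good = peak >= min_peak
        if good:
            # content moved by (dx, dy); the frame origin moves opposite
            ox, oy = ox - dx, oy - dy
        offsets.append((ox, oy))
        placements.append(FramePlacement(cur.frame_index, (ox, oy), peak, good))

    off = np.asarray(offsets)
    h, w = frames[0].shape
    min_xy = off.min(axis=0)
    shift = -min_xy
    extent = off.max(axis=0) - min_xy
    out_w = int(np.ceil(extent[0])) + w
    out_h = int(np.ceil(extent[1])) + h

    image = np.zeros((out_h, out_w))
    weight = np.zeros((out_h, out_w))
    feather = _feather_weight(frames[0])
    for frame, (ox, oy) in zip(frames, offsets):
        x0 = int(round(ox + shift[0]))
        y0 = int(round(oy + shift[1]))
        image[y0 : y0 + h, x0 : x0 + w] += frame.pixels * feather
        weight[y0 : y0 + h, x0 : x0 + w] += feather
    with np.errstate(invalid="ignore", divide="ignore"):
        image = np.where(weight > 0, image / np.maximum(weight, 1e-12), 0.0)
    placements = [
        FramePlacement(p.frame_index, (p.offset[0] + shift[0], p.offset[1] + shift[1]),
                       p.correlation_peak, p.chained_valid)
        for p in placements
    ]
    return MosaicCanvas(image=image, weight=weight, placements=placements, um_per_px=um_per_px)


@dataclass
class ScoreProfile:
    """Mean diagnostic score in consecutive bins of path arc length."""

    bins: list[tuple[float, float, int]]  # (arc_length_mm, mean_score, n_frames)
    bin_width_mm: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["arc_length_mm", "mean_score", "n_frames"])


def score_profile(
    track: ProbeTrack,
    scores: list[FrameScore],
    assoc: StreamAssociation,
    cal: CalibrationModel,
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
) -> ScoreProfile:
    """Average score versus cumulative distance along the imaging path.

    Arc length is accumulated along consecutive valid track entries; each
    scored micro frame is assigned the arc length of its associated
    widefield frame and scores are averaged in bins of ``bin_width_mm``.
    Bin positions are reported as the left bin edge; empty bins are omitted.
    """
    valid = track.valid_entries()
    if len(valid) < 2:
        raise InputError("score_profile needs at least 2 valid track entries")
    arc_by_frame: dict[int, float] = {}
    arc = 0.0
    prev = valid[0]
    arc_by_frame[prev.frame_index] = 0.0
    for e in valid[1:]:
        arc += pixels_to_mm(cal, (e.x - prev.x, e.y - prev.y))
        arc_by_frame[e.frame_index] = arc
        prev = e

    bin_sums: dict[int, float] = {}
    bin_counts: dict[int, int] = {}
    for fs in scores:
        wi = assoc.pairs.get(fs.frame_index)
        if wi is None or wi not in arc_by_frame:
            continue
        b = int(arc_by_frame[wi] // bin_width_mm)
        bin_sums[b] = bin_sums.get(b, 0.0) + fs.score
        bin_counts[b] = bin_counts.get(b, 0) + 1
    bins = [
        (b * bin_width_mm, bin_sums[b] / bin_counts[b], bin_counts[b])
        for b in sorted(bin_counts)
    ]
    return ScoreProfile(bins=bins, bin_width_mm=bin_width_mm)
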