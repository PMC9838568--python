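"""Probe-tip tracking in widefield video by color segmentation.

A colored dental ligature on the distal tip of the fiber-bundle probe gives
the tip a hue absent from oral mucosa (teal by default). Each widefield
frame is gated in HSV space, speckle is removed by a single 3x3 morphological
opening, and the centroid of the largest area-qualified connected component
is taken as the tip position. Short detection dropouts are bridged by linear
interpolation and the track is smoothed with a centered running median,
which is robust to single-frame misdetections without assuming a motion
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.color import rgb2hsv

from .exceptions import InputError
from .geometry import CalibrationModel, pixels_to_mm
from .riskmap import WidefieldFrame

__all__ = [
    "ColorGate",
    "ProbeTrack",
    "TrackEntry",
    "segment_marker",
    "locate_tip",
    "track_video",
    "evaluate_tracking",
    "default_teal_gate",
]


@dataclass(frozen=True)
class ColorGate:
    """HSV gate for the ligature marker.

    ``hue_range`` is in degrees and wrap-aware: ``(350, 10)`` matches hues
    near red across the 0/360 seam.
    """

    hue_range: tuple[float, float] = (160.0, 200.0)
    sat_min: float = 0.35
    val_min: float = 0.20
    min_area_px: int = 20
    max_area_px: int = 5000

    def __post_init__(self) -> None:
        lo, hi = self.hue_range
        if not (0 <= lo <= 360 and 0 <= hi <= 360):
            raise InputError("hue_range bounds must lie in [0, 360] degrees")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_min <= 1):
            raise InputError("sat_min and val_min must lie in [0, 1]")
        if not self.min_area_px < self.max_area_px:
            raise InputError("min_area_px must be < max_area_px")

    def hue_in_range(self, hue_deg: np.ndarray) -> np.ndarray:
        lo, hi = self.hue_range
        if lo <= hi:
            return (hue_deg >= lo) & (hue_deg <= hi)
        return (hue_deg >= lo) | (hue_deg <= hi)


def default_teal_gate() -> ColorGate:
    return ColorGate()


@dataclass
class TrackEntry:
    frame_index: int
    timestamp: float
    x: float
    y: float
    blob_area: float
    valid: bool
    interpolated: bool = False


@dataclass
class ProbeTrack:
    """Time series of probe-tip positions with validity flags."""

    entries: list[TrackEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [e.frame_index for e in self.entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InputError("frame_index must be strictly increasing")
        ts = [e.timestamp for e in self.entries]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise InputError("timestamps must be nondecreasing")

    def __len__(self) -> int:
        return len(self.entries)

    def valid_entries(self) -> list[TrackEntry]:
        return [e for e in self.entries if e.valid]

    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y); NaN where invalid."""
        out = np.full((len(self.entries), 2), np.nan)
        for i, e in enumerate(self.entries):
            if e.valid:
                out[i] = (e.x, e.y)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": [e.frame_index for e in self.entries],
                "timestamp_s": [e.timestamp for e in self.entries],
                "x_px": [e.x for e in self.entries],
                "y_px": [e.y for e in self.entries],
                "blob_area_px2": [e.blob_area for e in self.entries],
                "valid": [int(e.valid) for e in self.entries],
                "interpolated": [int(e.interpolated) for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProbeTrack":
        df = pd.read_csv(path)
        entries = [
            TrackEntry(
                frame_index=int(r.frame_index),
                timestamp=float(r.timestamp_s),
                x=float(r.x_px),
                y=float(r.y_px),
                blob_area=float(r.blob_area_px2),
                valid=bool(r.valid),
                interpolated=bool(getattr(r, "interpolated", 0)),
            )
            for r in df.itertuples()
        ]
        return cls(entries=entries)


def segment_marker(frame: WidefieldFrame, gate: ColorGate) -> np.ndarray:
    """Binary mask of gate-colored pixels, despeckled by one 3x3 opening."""
    rgb = frame.pixels
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsv = rgb2hsv(np.clip(rgb, 0.0, 1.0))
    hue_deg = hsv[..., 0] * 360.0
    mask = gate.hue_in_range(hue_deg) & (hsv[..., 1] >= gate.sat_min) & (hsv[..., 2] >= gate.val_min)
    return morphology.opening(mask, footprint=np.ones((3, 3), dtype=bool))


def locate_tip(marker_mask: np.ndarray, gate: ColorGate) -> tuple[float, float, float, bool]:
    """Centroid of the largest area-qualified 8-connected component.

    Returns ``(x, y, blob_area, valid)``; ``valid`` is False when no
    component falls inside ``[min_area_px, max_area_px]``. Area ties break
    toward the centroid with smaller y, then smaller x.
    """
    labels = measure.label(np.asarray(marker_mask).astype(bool), connectivity=2)
    best = None
    for region in measure.regionprops(labels):
        area = region.area
        if not gate.min_area_px <= area <= gate.max_area_px:
            continue
        cy, cx = region.centroid
        key = (-area, cy, cx)
        if best is None or key < best[0]:
            best = (key, (cx, cy, float(area)))
    if best is None:
        return (np.nan, np.nan, 0.0, False)
    cx, cy, area = best[1]
    return (float(cx), float(cy), area, True)


def _fill_gaps(entries: list[TrackEntry], max_gap: int) -> None:
    """Linearly interpolate invalid runs of length <= max_gap (in place)."""
    n = len(entries)
    i = 0
    while i < n:
        if entries[i].valid:
            i += 1
            continue
        j = i
        while j < n and not entries[j].valid:
            j += 1
        run = j - i
        if 0 < i and j < n and run <= max_gap:
            a, b = entries[i - 1], entries[j]
            denom = b.timestamp - a.timestamp
            for k in range(i, j):
                t = (entries[k].timestamp - a.timestamp) / denom if denom > 0 else (
                    (k - (i - 1)) / (run + 1)
                )
                entries[k].x = a.x + t * (b.x - a.x)
                entries[k].y = a.y + t * (b.y - a.y)
                entries[k].valid = True
                entries[k].interpolated = True
        i = j


def _median_smooth(entries: list[TrackEntry], window: int) -> None:
    """Centered running median over valid positions; edges shrink the window."""
    half = window // 2
    xs = np.array([e.x for e in entries])
    ys = np.array([e.y for e in entries])
    valid = np.array([e.valid for e in entries])
    sm_x = xs.copy()
    sm_y = ys.copy()
    for t in np.nonzero(valid)[0]:
        lo = max(0, t - half)
        hi = min(len(entries), t + half + 1)
        sel = valid[lo:hi]
        sm_x[t] = np.median(xs[lo:hi][sel])
        sm_y[t] = np.median(ys[lo:hi][sel])
    for t, e in enumerate(entries):
        if valid[t]:
            e.x = float(sm_x[t])
            e.y = float(sm_y[t])


def track_video(
    frames,
    gate: ColorGate,
    smooth_window: int = 5,
    max_gap: int = 5,
    timestamps=None,
) -> ProbeTrack:
    """Track the probe tip over a widefield frame sequence.

    Per-frame detection, gap interpolation (runs of <= ``max_gap`` invalid
    frames bridged linearly between valid flanks, flagged ``interpolated``)
    and centered running-median smoothing of width ``smooth_window`` (odd).
    The output for frame t depends only on frames up to
    ``t + (smooth_window - 1) / 2 + max_gap``, so the procedure is
    streaming-capable with bounded latency.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise InputError("track_video needs at least one frame")
    if smooth_window % 2 != 1 or smooth_window < 1:
        raise InputError("smooth_window must be a positive odd count")
    if max_gap < 0:
        raise InputError("max_gap must be >= 0")

    entries: list[TrackEntry] = []
    for i, frame in enumerate(frames):
        mask = segment_marker(frame, gate)
        x, y, area, valid = locate_tip(mask, gate)
        ts = frame.timestamp if timestamps is None else float(timestamps[i])
        entries.append(
            TrackEntry(
                frame_index=frame.frame_index if timestamps is None else i,
                timestamp=ts,
                x=x,
                y=y,
                blob_area=area,
                valid=valid,
            )
        )
    _fill_gaps(entries, max_gap)
    _median_smooth(entries, smooth_window)
    return ProbeTrack(entries=entries)


def evaluate_tracking(
    track: ProbeTrack, truth: ProbeTrack, cal: CalibrationModel
) -> tuple[float, float, float]:
    """Positional error of ``track`` against a reference ``truth`` track.

    Returns ``(mean_error_mm, p95_error_mm, valid_fraction)``; errors are
    computed over frames valid in both tracks and converted to millimeters
    with the widefield calibration. ``valid_fraction`` is the fraction of
    truth-valid frames the tracker marked valid.
    """
    t_by_idx = {e.frame_index: e for e in track.entries}
    errors = []
    n_truth_valid = 0
    n_both = 0
    for te in truth.entries:
        if not te.valid:
            continue
        n_truth_valid += 1
        e = t_by_idx.get(te.frame_index)
        if e is None or not e.valid:
            continue
        n_both += 1
        errors.append(pixels_to_mm(cal, (e.x - te.x, e.y - te.y)))
    if n_both == 0:
        raise InputError("no frames are valid in both tracks")
    errors = np.asarray(errors)
    return (
        float(errors.mean()),
        float(np.percentile(errors, 95)),
        n_both / n_truth_valid,
    )
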