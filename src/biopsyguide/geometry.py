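"""Coordinate frames, physical calibration and camera-projector homography.

The guidance system images the oral cavity with a widefield camera and
projects a binary guidance mask back onto tissue with a DLP projector.  In
software the projection path reduces to a planar homography between the
camera image plane and the projector image plane; this module owns that
mapping plus the pixel-to-millimeter calibration used everywhere distances
are reported.

Coordinate convention (shared by every module in this package): 0-based
pixel coordinates ``(x, y)`` with ``x`` rightward, ``y`` downward and the
origin at the center of the top-left pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import EstimationError, InputError

__all__ = [
    "CalibrationModel",
    "PlanarHomography",
    "estimate_homography",
    "apply_homography",
    "warp_binary_mask",
    "pixels_to_mm",
]

#: widefield frame during multimodal imaging: 960x600 px spanning ~80x50 mm
DEFAULT_FRAME_WIDTH = 960
DEFAULT_FRAME_HEIGHT = 600
DEFAULT_MM_PER_PX = 80.0 / 960.0  # 0.0833 mm/px

_DET_EPS = 1e-12


@dataclass(frozen=True)
class CalibrationModel:
    """Physical calibration of the widefield frame.

    Defaults correspond to an 8x5 cm field of view imaged at 960x600 px,
    i.e. 0.0833 mm/px in both axes.
    """

    frame_width_px: int = DEFAULT_FRAME_WIDTH
    frame_height_px: int = DEFAULT_FRAME_HEIGHT
    mm_per_px_x: float = DEFAULT_MM_PER_PX
    mm_per_px_y: float = DEFAULT_MM_PER_PX

    def __post_init__(self) -> None:
        for name in ("frame_width_px", "frame_height_px", "mm_per_px_x", "mm_per_px_y"):
            if not getattr(self, name) > 0:
                raise InputError(f"CalibrationModel.{name} must be strictly positive")

    @property
    def field_width_mm(self) -> float:
        return self.frame_width_px * self.mm_per_px_x

    @property
    def field_height_mm(self) -> float:
        return self.frame_height_px * self.mm_per_px_y


def pixels_to_mm(cal: CalibrationModel, displacement: tuple[float, float]) -> float:
    """Euclidean length in mm of a pixel displacement ``(dx_px, dy_px)``."""
    dx, dy = displacement
    return float(np.hypot(dx * cal.mm_per_px_x, dy * cal.mm_per_px_y))


@dataclass(frozen=True)
class PlanarHomography:
    """3x3 projective transform, camera plane -> projector plane.

    The matrix is stored normalized with the bottom-right entry fixed to 1.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InputError("homography matrix must be 3x3")
        if not np.all(np.isfinite(m)):
            raise InputError("homography matrix must be finite")
        if abs(m[2, 2]) < _DET_EPS:
            raise InputError("homography matrix has vanishing h33; cannot normalize")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) < _DET_EPS:
            raise InputError("homography matrix is singular")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "PlanarHomography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "PlanarHomography":
        m = np.eye(3)
        m[0, 2] = tx
        m[1, 2] = ty
        return cls(m)

    def inverse(self) -> "PlanarHomography":
        return PlanarHomography(np.linalg.inv(self.matrix))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.matrix.ravel().tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanarHomography":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["matrix"], dtype=float).reshape(3, 3))


def _as_points(pts) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError("point set must have shape (N, 2)")
    if not np.all(np.isfinite(arr)):
        raise InputError("point coordinates must be finite")
    return arr


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity normalization: centroid at origin, RMS distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    scale = np.sqrt(2.0) / rms if rms > 0 else 1.0
    t = np.array(
        [
            [scale, 0.0, -scale * centroid[0]],
            [0.0, scale, -scale * centroid[1]],
            [0.0, 0.0, 1.0],
        ]
    )
    return t


def _any_three_collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                scale = max(np.abs([b - a, c - a]).max(), 1.0)
                if abs(cross) <= tol * scale * scale:
                    return True
    return False


def estimate_homography(src, dst, method: str = "least_squares") -> PlanarHomography:
    """Estimate the camera->projector homography from point correspondences.

    Parameters
    ----------
    src, dst
        Paired (N, 2) pixel coordinates, N >= 4.
    method
        ``"exact4"`` solves the interpolating homography from exactly four
        correspondences; ``"least_squares"`` runs normalized DLT minimizing
        algebraic error over all correspondences.
    """
    src = _as_points(src)
    dst = _as_points(dst)
    if len(src) != len(dst):
        raise InputError("src and dst must have the same number of points")
    if len(src) < 4:
        raise InputError("homography estimation needs at least 4 correspondences")
    if method == "exact4":
        if len(src) != 4:
            raise InputError("method 'exact4' requires exactly 4 correspondences")
        if _any_three_collinear(src) or _any_three_collinear(dst):
            raise EstimationError("degenerate configuration: 3 collinear points")
    elif method != "least_squares":
        raise InputError(f"unknown method {method!r}")

    t_src = _normalization(src)
    t_dst = _normalization(dst)
    s = apply_homography(PlanarHomography(t_src), src)
    d = apply_homography(PlanarHomography(t_dst), dst)

    # DLT system: each correspondence contributes two rows of A h = 0.
    n = len(s)
    a = np.zeros((2 * n, 9))
    a[0::2, 0] = -s[:, 0]
    a[0::2, 1] = -s[:, 1]
    a[0::2, 2] = -1.0
    a[0::2, 6] = d[:, 0] * s[:, 0]
    a[0::2, 7] = d[:, 0] * s[:, 1]
    a[0::2, 8] = d[:, 0]
    a[1::2, 3] = -s[:, 0]
    a[1::2, 4] = -s[:, 1]
    a[1::2, 5] = -1.0
    a[1::2, 6] = d[:, 1] * s[:, 0]
    a[1::2, 7] = d[:, 1] * s[:, 1]
    a[1::2, 8] = d[:, 1]

    _, sv, vt = np.linalg.svd(a)
    # A rank deficit beyond the expected one-dimensional null space signals a
    # degenerate configuration (duplicate or collinear points).
    if sv[0] > 0 and sv[-2] / sv[0] < 1e-10:
        raise EstimationError("degenerate point configuration for homography")
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h_norm @ t_src
    if abs(h[2, 2]) < _DET_EPS:
        raise EstimationError("estimated homography is not normalizable")
    try:
        return PlanarHomography(h)
    except InputError as exc:  # singular estimate
        raise EstimationError(str(exc)) from exc


def apply_homography(h: PlanarHomography, pts) -> np.ndarray:
    """Apply ``h`` pointwise; order preserved.

    Points mapping to infinity (homogeneous scale ~ 0) are flagged by NaN
    coordinates.
    """
    pts = _as_points(pts)
    hom = np.column_stack([pts, np.ones(len(pts))])
    mapped = hom @ h.matrix.T
    w = mapped[:, 2]
    out = np.full_like(pts, np.nan)
    ok = np.abs(w) > _DET_EPS
    out[ok] = mapped[ok, :2] / w[ok, None]
    return out


def warp_binary_mask(
    h: PlanarHomography, mask: np.ndarray, out_width: int, out_height: int
) -> np.ndarray:
    """Warp a binary mask into projector coordinates.

    Inverse-mapped nearest-neighbor warp: each output pixel samples the source
    mask at the inverse-transformed location. Output is strictly boolean;
    pixels mapping outside the source are 0. Nearest-neighbor keeps the
    projected guidance map free of gray halos.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError("mask must be 2-D")
    mask = mask.astype(bool)
    inv = h.inverse()

    xs, ys = np.meshgrid(np.arange(out_width), np.arange(out_height))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = apply_homography(inv, pts)
    sx = np.rint(src[:, 0])
    sy = np.rint(src[:, 1])
    valid = (
        np.isfinite(sx)
        & np.isfinite(sy)
        & (sx >= 0)
        & (sx < mask.shape[1])
        & (sy >= 0)
        & (sy < mask.shape[0])
    )
    out = np.zeros(out_height * out_width, dtype=bool)
    out[valid] = mask[sy[valid].astype(int), sx[valid].astype(int)]
    return out.reshape(out_height, out_width)
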