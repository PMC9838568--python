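"""Widefield autofluorescence cancer risk maps.

Neoplastic oral mucosa loses green (collagen) autofluorescence and gains red
(porphyrin) emission under 405-nm excitation. The per-pixel normalized
red-to-green (RG) intensity ratio therefore serves as a cancer risk score:
the raw ratio R/(G+eps) is computed inside a clinician-drawn mucosa outline
(teeth, gloves and retractors excluded) and self-normalized by the mean (or
median) ratio over the outline, so a value of 1 means "average mucosa" and
elevated values flag risk. A rendered heatmap overlays the risk on the
acquired image with warmer colors at higher risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import matplotlib

from .exceptions import InputError

__all__ = [
    "WidefieldFrame",
    "MucosaMask",
    "RiskMap",
    "polygon_to_mask",
    "compute_rg_ratio",
    "threshold_risk",
    "render_risk_heatmap",
]

DEFAULT_GREEN_EPS = 1.0  # intensity units; guards against G = 0 pixels


@dataclass
class WidefieldFrame:
    """One widefield RGB frame, white-light ("WL") or autofluorescence ("AF")."""

    pixels: np.ndarray  # H x W x 3, non-negative intensities
    timestamp: float = 0.0
    modality: str = "AF"
    frame_index: int = 0

    def __post_init__(self) -> None:
        # 8/16-bit images pass through untouched; floats are kept at float32
        # so whole-session frame lists stay compact
        self.pixels = np.asarray(self.pixels)
        if np.issubdtype(self.pixels.dtype, np.floating):
            self.pixels = self.pixels.astype(np.float32, copy=False)
            if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
                raise InputError("WidefieldFrame intensities must be finite and >= 0")
        elif not np.issubdtype(self.pixels.dtype, np.unsignedinteger):
            raise InputError("WidefieldFrame.pixels must be float or unsigned integer")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError("WidefieldFrame.pixels must be H x W x 3")
        if self.modality not in ("WL", "AF"):
            raise InputError("modality must be 'WL' or 'AF'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MucosaMask:
    mask: np.ndarray  # H x W bool
    source_polygon: np.ndarray | None = None  # (N, 2) vertices, (x, y)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise InputError("MucosaMask.mask must be 2-D")


@dataclass
class RiskMap:
    """Normalized RG ratio field; NaN outside the mucosa mask."""

    rg: np.ndarray
    mask: MucosaMask
    normalization_constant: float
    epsilon: float = DEFAULT_GREEN_EPS
    norm_stat: str = "mean"


def _on_segment(px, py, a, b, tol=1e-9):
    """Boolean array: does pixel-center (px, py) lie on segment a-b?"""
    ax, ay = a
    bx, by = b
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    seg_len = max(np.hypot(bx - ax, by - ay), tol)
    within = (
        (px >= min(ax, bx) - tol)
        & (px <= max(ax, bx) + tol)
        & (py >= min(ay, by) - tol)
        & (py <= max(ay, by) + tol)
    )
    return (np.abs(cross) <= tol * seg_len) & within


def polygon_to_mask(vertices, width: int, height: int) -> MucosaMask:
    """Rasterize a closed polygon outline into a binary mucosa mask.

    Even-odd rule evaluated at pixel centers; pixels whose center lies on the
    polygon boundary are included. Vertices are clipped to the frame bounds
    before rasterization.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise InputError("vertices must be (N, 2)")
    if len(verts) < 3:
        raise InputError("a polygon outline needs at least 3 vertices")
    verts = verts.copy()
    verts[:, 0] = np.clip(verts[:, 0], 0, width - 1)
    verts[:, 1] = np.clip(verts[:, 1], 0, height - 1)
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area == 0:
        raise InputError("polygon has zero area")

    px, py = np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))
    inside = np.zeros((height, width), dtype=bool)
    boundary = np.zeros_like(inside)
    n = len(verts)
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        boundary |= _on_segment(px, py, (ax, ay), (bx, by))
        if ay == by:
            continue
        # even-odd ray cast: horizontal ray to +x from the pixel center
        crosses = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px < x_at)
    return MucosaMask(mask=inside | boundary, source_polygon=verts)


def compute_rg_ratio(
    af: WidefieldFrame,
    mask: MucosaMask,
    norm_stat: str = "mean",
    epsilon: float = DEFAULT_GREEN_EPS,
) -> RiskMap:
    """Normalized red-to-green ratio map over the mucosa mask.

    Raw ratio ``r = R / (G + epsilon)`` per pixel; the normalization constant
    is the ``norm_stat`` (mean or median) of ``r`` over the mask, and the
    returned field is ``r`` divided by it inside the mask, NaN outside.
    Self-normalization makes the map invariant to global illumination scale.
    """
    if af.modality != "AF":
        raise InputError("compute_rg_ratio expects an autofluorescence frame")
    if af.shape != mask.mask.shape:
        raise InputError("frame and mask dimensions differ")
    if not mask.mask.any():
        raise InputError("mucosa mask is empty")
    if norm_stat not in ("mean", "median"):
        raise InputError("norm_stat must be 'mean' or 'median'")
    red = af.pixels[..., 0]
    green = af.pixels[..., 1]
    if green[mask.mask].max() == 0:
        raise InputError("green channel is all zero inside the mask; AF image uninterpretable")
    r = red / (green + epsilon)
    stat = np.mean if norm_stat == "mean" else np.median
    norm = float(stat(r[mask.mask]))
    if norm <= 0:
        raise InputError("normalization constant is non-positive; AF image uninterpretable")
    rg = np.full(r.shape, np.nan)
    rg[mask.mask] = r[mask.mask] / norm
    return RiskMap(rg=rg, mask=mask, normalization_constant=norm, epsilon=epsilon, norm_stat=norm_stat)


def threshold_risk(risk: RiskMap, tau_rg: float) -> np.ndarray:
    """Pixels inside the mask whose normalized RG ratio reaches ``tau_rg``."""
    if tau_rg < 0:
        raise InputError("tau_rg must be >= 0")
    rg = np.where(np.isfinite(risk.rg), risk.rg, -np.inf)
    return risk.mask.mask & (rg >= tau_rg)


def render_risk_heatmap(
    risk: RiskMap,
    base: WidefieldFrame,
    colormap: str = "jet",
    alpha: float = 0.5,
    display_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Alpha-blend a colormapped risk heatmap over a base image.

    Returns a float RGB image in [0, 1]. Outside the mucosa mask the base is
    unmodified. ``display_range`` defaults to the 2nd-98th percentile of the
    risk values inside the mask (robust contrast).
    """
    if base.shape != risk.rg.shape:
        raise InputError("base frame and risk map dimensions differ")
    if not 0 <= alpha <= 1:
        raise InputError("alpha must be in [0, 1]")
    m = risk.mask.mask
    vals = risk.rg[m]
    if display_range is None:
        lo, hi = np.percentile(vals, [2, 98])
        if hi <= lo:  # constant field: any range renders a uniform color
            hi = lo + 1e-6
    else:
        lo, hi = display_range
        if lo >= hi:
            raise InputError("display_range lo must be < hi")

    base_img = base.pixels / 255.0 if base.pixels.max() > 1.0 else base.pixels.copy()
    base_img = np.clip(base_img, 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    t = np.clip((risk.rg - lo) / (hi - lo), 0.0, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    colors = cmap(t)[..., :3]
    out = base_img.copy()
    out[m] = (1.0 - alpha) * base_img[m] + alpha * colors[m]
    return out
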