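"""Synthetic imaging sessions with ground truth.

A phantom session emulates one multimodal acquisition: a white-light /
autofluorescence widefield image pair bearing an elliptical lesion (red
autofluorescence gain, green loss), widefield video of a colored probe
marker moving along a trajectory across the lesion, and microendoscopy
frames of stained nuclei whose morphometric regime (normal: sparse,
regularly spaced nuclei; dysplastic: crowded, enlarged nuclei) is decided
by whether the true probe tip lies inside the lesion. Everything is seeded
and bit-reproducible, and the generator returns the full ground truth
(lesion mask, true track, per-frame regime labels and nuclei), so every
pipeline stage can be evaluated without real data.

No analysis module reads the ground truth; it is consumed only by
evaluation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .exceptions import InputError
from .geometry import DEFAULT_MM_PER_PX
from .riskmap import WidefieldFrame
from .scoring import (
    DEFAULT_FOV_RADIUS,
    DEFAULT_MICRO_HEIGHT,
    DEFAULT_MICRO_WIDTH,
    DEFAULT_UM_PER_PX,
    MicroFrame,
    NucleiSet,
)
from .tracking import ProbeTrack, TrackEntry

__all__ = [
    "PhantomSpec",
    "AFModel",
    "MarkerSpec",
    "TrajectorySpec",
    "RateSpec",
    "MicroModel",
    "LesionSpec",
    "SessionGroundTruth",
    "SessionData",
    "generate_af_pair",
    "generate_micro_frame",
    "generate_session",
]


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float] = (600.0, 300.0)
    semi_axes: tuple[float, float] = (110.0, 70.0)
    rotation_deg: float = 20.0


@dataclass(frozen=True)
class AFModel:
    """Autofluorescence contrast model: green loss and red gain inside the lesion."""

    green_bg: float = 140.0
    red_bg: float = 60.0
    lesion_red_gain: float = 2.0
    lesion_green_loss: float = 0.6
    noise_sd: float = 5.1  # 2% of the 8-bit dynamic range

    def __post_init__(self) -> None:
        if self.lesion_red_gain < 1.0 or not 0.0 < self.lesion_green_loss <= 1.0:
            raise InputError("lesion_red_gain must be >= 1 and lesion_green_loss in (0, 1]")


@dataclass(frozen=True)
class MarkerSpec:
    hue_deg: float = 180.0  # teal, absent from oral mucosa imagery
    radius_px: float = 8.0


@dataclass(frozen=True)
class TrajectorySpec:
    waypoints: tuple[tuple[float, float], ...] = ((250.0, 300.0), (600.0, 300.0), (850.0, 350.0))
    speed_mm_s: float = 8.0


@dataclass(frozen=True)
class RateSpec:
    widefield_fps: float = 20.0
    micro_fps: float = 90.0

    def __post_init__(self) -> None:
        if self.micro_fps < self.widefield_fps:
            raise InputError("micro_fps must be >= widefield_fps")


@dataclass(frozen=True)
class MicroModel:
    """Two-regime nuclei model for microendoscopy frames."""

    normal_density_per_mm2: float = 150.0
    dysplastic_density_mult: float = 3.0
    normal_radius_um: tuple[float, float] = (4.0, 0.5)  # mean, sd
    dysplastic_radius_um: tuple[float, float] = (6.0, 0.75)
    background: float = 20.0
    nucleus_peak: float = 160.0
    noise_sd: float = 5.1
    transition_width_px: float = 0.0  # optional density ramp at the lesion edge

    def __post_init__(self) -> None:
        if self.normal_density_per_mm2 <= 0 or self.dysplastic_density_mult < 1.0:
            raise InputError("densities must be positive; dysplastic_density_mult >= 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of a synthetic imaging session."""

    seed: int = 0
    widefield_dims: tuple[int, int] = (960, 600)  # (width, height)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    af_model: AFModel = field(default_factory=AFModel)
    marker: MarkerSpec = field(default_factory=MarkerSpec)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    rates: RateSpec = field(default_factory=RateSpec)
    micro_model: MicroModel = field(default_factory=MicroModel)
    micro_dims: tuple[int, int] = (DEFAULT_MICRO_WIDTH, DEFAULT_MICRO_HEIGHT)
    fov_radius_px: float = DEFAULT_FOV_RADIUS
    um_per_px: float = DEFAULT_UM_PER_PX
    mm_per_px: float = DEFAULT_MM_PER_PX
    duration_s: float = 5.0

    def __post_init__(self) -> None:
        w, h = self.widefield_dims
        cx, cy = self.lesion.center
        a, b = self.lesion.semi_axes
        r = max(a, b)
        if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
            raise InputError("lesion ellipse must lie inside the widefield frame")
        for x, y in self.trajectory.waypoints:
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise InputError("trajectory waypoints must lie inside the widefield frame")
        if self.duration_s <= 0:
            raise InputError("duration_s must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionGroundTruth:
    lesion_mask: np.ndarray
    true_track: ProbeTrack
    regime_labels: list[str]  # per micro frame: "normal" | "dysplastic"
    true_nuclei: list[NucleiSet]
    micro_timestamps: np.ndarray
    widefield_timestamps: np.ndarray


@dataclass
class SessionData:
    spec: PhantomSpec
    wl: WidefieldFrame
    af: WidefieldFrame
    lesion_mask: np.ndarray
    widefield_frames: list[WidefieldFrame]
    micro_frames: list[MicroFrame]
    truth: SessionGroundTruth
    manifest: dict


def _lesion_mask(spec: PhantomSpec) -> np.ndarray:
    w, h = spec.widefield_dims
    cx, cy = spec.lesion.center
    a, b = spec.lesion.semi_axes
    theta = np.deg2rad(spec.lesion.rotation_deg)
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - cx
    dy = ys - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    return u**2 + v**2 <= 1.0


def _wl_base(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Textured pink mucosa rendering (content unused by analysis)."""
    w, h = spec.widefield_dims
    base = np.empty((h, w, 3))
    base[..., 0] = 205.0
    base[..., 1] = 150.0
    base[..., 2] = 150.0
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=12.0) * 60.0
    base += texture[..., None]
    return np.clip(base, 0.0, 255.0)


def generate_af_pair(spec: PhantomSpec) -> tuple[WidefieldFrame, WidefieldFrame, np.ndarray]:
    """Widefield WL/AF image pair plus the ground-truth lesion mask.

    Inside the lesion the AF red channel is multiplied by ``lesion_red_gain``
    and the green channel by ``lesion_green_loss``, with a ~2 px feathered
    boundary; additive Gaussian noise is clipped at the 8-bit range.
    """
    w, h = spec.widefield_dims
    lesion = _lesion_mask(spec)
    alpha = gaussian_filter(lesion.astype(float), sigma=1.0)
    m = spec.af_model

    rng = np.random.default_rng([spec.seed, 1])
    af = np.empty((h, w, 3))
    af[..., 0] = m.red_bg * (1.0 + alpha * (m.lesion_red_gain - 1.0))
    af[..., 1] = m.green_bg * (1.0 - alpha * (1.0 - m.lesion_green_loss))
    af[..., 2] = 0.15 * m.green_bg
    af += rng.normal(0.0, m.noise_sd, size=af.shape)
    af = np.rint(np.clip(af, 0.0, 255.0)).astype(np.uint8)

    rng_wl = np.random.default_rng([spec.seed, 2])
    wl = _wl_base(spec, rng_wl)
    wl += rng_wl.normal(0.0, m.noise_sd, size=wl.shape)
    wl = np.rint(np.clip(wl, 0.0, 255.0)).astype(np.uint8)

    return (
        WidefieldFrame(pixels=wl, timestamp=0.0, modality="WL", frame_index=0),
        WidefieldFrame(pixels=af, timestamp=0.0, modality="AF", frame_index=0),
        lesion,
    )


def _hardcore_points(
    rng: np.random.Generator,
    n_target: int,
    center: tuple[float, float],
    radius: float,
    min_sep: float,
) -> np.ndarray:
    """Dart-throwing hard-core point process inside a circle."""
    cx, cy = center
    pts: list[tuple[float, float]] = []
    max_attempts = 400 * max(n_target, 1)
    attempts = 0
    rejected_in_a_row = 0
    while len(pts) < n_target and attempts < max_attempts and rejected_in_a_row < 500:
        attempts += 1
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = radius * np.sqrt(rng.uniform())
        x = cx + rad * np.cos(ang)
        y = cy + rad * np.sin(ang)
        if pts:
            arr = np.asarray(pts)
            if np.min((arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2) < min_sep**2:
                rejected_in_a_row += 1
                continue
        pts.append((x, y))
        rejected_in_a_row = 0
    if len(pts) < n_target:
        raise InputError(
            f"hard-core placement failed: placed {len(pts)}/{n_target} nuclei "
            f"(min separation {min_sep:.1f} px too large for the density)"
        )
    return np.asarray(pts).reshape(-1, 2)


def generate_micro_frame(
    spec: PhantomSpec,
    regime: str,
    seed_offset: int,
    density_override: float | None = None,
) -> tuple[MicroFrame, NucleiSet]:
    """One microendoscopy frame of Gaussian-blob nuclei plus its ground truth.

    Nucleus centers follow a hard-core point process (minimum separation of
    one nucleus diameter for the normal regime, half a diameter for the
    dysplastic one) at the regime's density inside the field-of-view circle.
    """
    if regime not in ("normal", "dysplastic"):
        raise InputError("regime must be 'normal' or 'dysplastic'")
    m = spec.micro_model
    w, h = spec.micro_dims
    center = (w / 2.0, h / 2.0)
    r_fov = spec.fov_radius_px

    if regime == "normal":
        density = m.normal_density_per_mm2
        radius_mean, radius_sd = m.normal_radius_um
        sep_diameters = 1.0
    else:
        density = m.normal_density_per_mm2 * m.dysplastic_density_mult
        radius_mean, radius_sd = m.dysplastic_radius_um
        sep_diameters = 0.5
    if density_override is not None:
        density = density_override

    rng = np.random.default_rng([spec.seed, 4, seed_offset])
    fov_area_mm2 = np.pi * (r_fov * spec.um_per_px / 1000.0) ** 2
    n = int(rng.poisson(density * fov_area_mm2))
    min_sep_px = sep_diameters * 2.0 * radius_mean / spec.um_per_px
    centers = _hardcore_points(rng, n, center, r_fov - 3.0, min_sep_px)

    img = np.zeros((h, w))
    ys, xs = np.ogrid[0:h, 0:w]
    fov = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= r_fov**2
    img[fov] = m.background

    radii_um = np.maximum(rng.normal(radius_mean, radius_sd, size=n), 1.0)
    amps = m.nucleus_peak * np.clip(rng.normal(1.0, 0.1, size=n), 0.5, 1.5)
    areas = np.pi * (radii_um / spec.um_per_px) ** 2
    eccs = np.zeros(n)
    for (x, y), r_um, amp in zip(centers, radii_um, amps):
        sigma = 0.6 * r_um / spec.um_per_px
        half = int(np.ceil(3 * sigma))
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        px, py = np.meshgrid(np.arange(x0c, x1c), np.arange(y0c, y1c))
        img[y0c:y1c, x0c:x1c] += amp * np.exp(
            -((px - x) ** 2 + (py - y) ** 2) / (2.0 * sigma**2)
        )
    img += rng.normal(0.0, m.noise_sd, size=img.shape)
    img[~fov] *= 0.05  # circular vignette outside the field of view
    img = np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)

    frame = MicroFrame(
        pixels=img,
        timestamp=0.0,
        frame_index=seed_offset,
        fov_center=center,
        fov_radius=r_fov,
    )
    nuclei = (
        NucleiSet(centers, areas, eccs) if n > 0 else NucleiSet.empty()
    )
    return frame, nuclei


def _trajectory_position(spec: PhantomSpec, t: float) -> tuple[float, float]:
    """Tip position at time t: constant speed along the waypoint polyline."""
    pts = np.asarray(spec.trajectory.waypoints, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    speed_px = spec.trajectory.speed_mm_s / spec.mm_per_px
    s = min(speed_px * t, cum[-1])
    i = int(np.searchsorted(cum[1:], s, side="right"))
    i = min(i, len(seg) - 1)
    frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    return (float(pts[i, 0] + frac * seg[i, 0]), float(pts[i, 1] + frac * seg[i, 1]))


def _draw_marker(img: np.ndarray, pos: tuple[float, float], marker: MarkerSpec) -> None:
    h, w = img.shape[:2]
    rgb = hsv2rgb(np.array([[[marker.hue_deg / 360.0, 0.85, 0.9]]]))[0, 0] * 255.0
    x, y = pos
    r = marker.radius_px
    x0, x1 = max(int(x - r - 1), 0), min(int(x + r + 2), w)
    y0, y1 = max(int(y - r - 1), 0), min(int(y + r + 2), h)
    px, py = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    disc = (px - x) ** 2 + (py - y) ** 2 <= r**2
    region = img[y0:y1, x0:x1]
    region[disc] = rgb


def _signed_lesion_distance(lesion_mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import distance_transform_edt

    inside = distance_transform_edt(lesion_mask)
    outside = distance_transform_edt(~lesion_mask)
    return inside - outside


def generate_session(spec: PhantomSpec, include_micro: bool = True) -> SessionData:
    """Simulate a full multimodal imaging session.

    The probe tip moves along the trajectory at the stated speed; widefield
    frames carry the marker disc drawn at the true tip over the WL phantom,
    and micro frames take their regime from ground-truth lesion membership
    at the interpolated tip position. Both streams share one clock with
    timestamps on exact frame-rate grids.
    """
    wl, af, lesion = generate_af_pair(spec)

    n_wide = int(round(spec.duration_s * spec.rates.widefield_fps))
    n_micro = int(round(spec.duration_s * spec.rates.micro_fps))
    wide_ts = np.arange(n_wide) / spec.rates.widefield_fps
    micro_ts = np.arange(n_micro) / spec.rates.micro_fps

    m = spec.af_model
    widefield_frames: list[WidefieldFrame] = []
    truth_entries: list[TrackEntry] = []
    for i, t in enumerate(wide_ts):
        pos = _trajectory_position(spec, float(t))
        rng = np.random.default_rng([spec.seed, 3, i])
        img = wl.pixels.astype(np.float32, copy=True)
        _draw_marker(img, pos, spec.marker)
        noise = rng.standard_normal(img.shape, dtype=np.float32)
        noise *= m.noise_sd
        img += noise
        np.clip(img, 0.0, 255.0, out=img)
        img_u8 = np.rint(img).astype(np.uint8)
        widefield_frames.append(
            WidefieldFrame(pixels=img_u8, timestamp=float(t), modality="WL", frame_index=i)
        )
        truth_entries.append(
            TrackEntry(frame_index=i, timestamp=float(t), x=pos[0], y=pos[1],
                       blob_area=np.pi * spec.marker.radius_px**2, valid=True)
        )

    micro_frames: list[MicroFrame] = []
    regime_labels: list[str] = []
    true_nuclei: list[NucleiSet] = []
    ramp = spec.micro_model.transition_width_px
    sdist = _signed_lesion_distance(lesion) if ramp > 0 else None
    if include_micro:
        for i, t in enumerate(micro_ts):
            pos = _trajectory_position(spec, float(t))
            px = int(round(pos[0]))
            py = int(round(pos[1]))
            inside = bool(lesion[py, px])
            regime = "dysplastic" if inside else "normal"
            density_override = None
            if sdist is not None:
                frac = float(np.clip(sdist[py, px] / ramp + 0.5, 0.0, 1.0))
                mm = spec.micro_model
                density_override = mm.normal_density_per_mm2 * (
                    1.0 + (mm.dysplastic_density_mult - 1.0) * frac
                )
            frame, nuclei = generate_micro_frame(spec, regime, i, density_override)
            frame.timestamp = float(t)
            micro_frames.append(frame)
            regime_labels.append(regime)
            true_nuclei.append(nuclei)

    truth = SessionGroundTruth(
        lesion_mask=lesion,
        true_track=ProbeTrack(entries=truth_entries),
        regime_labels=regime_labels,
        true_nuclei=true_nuclei,
        micro_timestamps=micro_ts,
        widefield_timestamps=wide_ts,
    )
    manifest = {
        "seed": spec.seed,
        "n_widefield_frames": n_wide,
        "n_micro_frames": n_micro if include_micro else 0,
        "duration_s": spec.duration_s,
        "spec": spec.to_dict(),
    }
    return SessionData(
        spec=spec,
        wl=wl,
        af=af,
        lesion_mask=lesion,
        widefield_frames=widefield_frames,
        micro_frames=micro_frames,
        truth=truth,
        manifest=manifest,
    )
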