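"""Multimodal fusion: score aggregation onto anatomy and biopsy guidance maps.

The microscope runs at a much higher frame rate than the widefield camera,
so each widefield frame (and hence each tracked probe position) receives
many microscopy scores. Scores are deposited onto every pixel within a
small disc around the tracked tip — the probe samples a finite contact
area — and the per-pixel running sum/count gives an average score field on
demand.

The biopsy guidance map is the conjunction of two clinician-set thresholds:
a pixel is recommended for biopsy when it lies on outlined mucosa, has been
visited by the probe, its normalized RG ratio reaches ``tau_rg`` and its
mean microscopy score reaches ``tau_mtn``. Because the risk map and score
field are cached, changing thresholds only re-applies two comparisons and a
new guidance map is produced interactively without touching raw video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .geometry import PlanarHomography, warp_binary_mask
from .riskmap import RiskMap, threshold_risk
from .scoring import FrameScore
from .tracking import ProbeTrack

__all__ = [
    "StreamAssociation",
    "ScoreField",
    "GuidanceThresholds",
    "GuidanceMap",
    "associate_frames",
    "accumulate_scores",
    "compute_guidance_map",
    "update_thresholds",
    "project_guidance",
    "disc_offsets",
]

#: probe field of view is ~790 um across -> radius ~4.7 px at 0.0833 mm/px
DEFAULT_FOOTPRINT_RADIUS_PX = 5
DEFAULT_ASSOCIATION_TOLERANCE_S = 0.1


@dataclass
class StreamAssociation:
    """Micro-frame -> widefield-frame pairing by nearest timestamp."""

    pairs: dict[int, int]  # micro frame index -> widefield frame index
    tolerance: float


def associate_frames(
    micro_timestamps, widefield_timestamps, tolerance: float = DEFAULT_ASSOCIATION_TOLERANCE_S
) -> StreamAssociation:
    """Pair each micro timestamp with the nearest-in-time widefield frame.

    Pairs farther apart than ``tolerance`` seconds are dropped; exact ties
    break toward the earlier widefield frame.
    """
    micro = np.asarray(micro_timestamps, dtype=float)
    wide = np.asarray(widefield_timestamps, dtype=float)
    if micro.size == 0 or wide.size == 0:
        raise InputError("timestamp lists must be nonempty")
    if np.any(np.diff(micro) < 0) or np.any(np.diff(wide) < 0):
        raise InputError("timestamp lists must be nondecreasing")

    right = np.searchsorted(wide, micro)
    left = np.clip(right - 1, 0, len(wide) - 1)
    right = np.clip(right, 0, len(wide) - 1)
    d_left = np.abs(micro - wide[left])
    d_right = np.abs(micro - wide[right])
    # ties (d_left == d_right) go to the earlier frame, i.e. `left`
    choose_right = d_right < d_left
    chosen = np.where(choose_right, right, left)
    dt = np.where(choose_right, d_right, d_left)
    pairs = {int(mi): int(wi) for mi, (wi, d) in enumerate(zip(chosen, dt)) if d <= tolerance}
    return StreamAssociation(pairs=pairs, tolerance=tolerance)


@dataclass
class ScoreField:
    """Per-pixel running sum and count of deposited frame scores."""

    sum: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.sum = np.asarray(self.sum, dtype=float)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.sum.shape != self.count.shape:
            raise InputError("sum and count shapes differ")

    @classmethod
    def zeros(cls, dims: tuple[int, int]) -> "ScoreField":
        h, w = dims
        return cls(np.zeros((h, w)), np.zeros((h, w), dtype=np.int64))

    def mean(self) -> np.ndarray:
        """Per-pixel average score; NaN where no score was deposited."""
        out = np.full(self.sum.shape, np.nan)
        visited = self.count > 0
        out[visited] = self.sum[visited] / self.count[visited]
        return out

    @property
    def visited(self) -> np.ndarray:
        return self.count > 0


def disc_offsets(radius_px: int) -> np.ndarray:
    """(K, 2) integer (dx, dy) offsets of the disc of given radius (0 -> origin only)."""
    r = int(radius_px)
    dys, dxs = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dxs**2 + dys**2 <= r**2
    return np.column_stack([dxs[keep], dys[keep]])


def accumulate_scores(
    track: ProbeTrack,
    scores: list[FrameScore],
    assoc: StreamAssociation,
    footprint_radius_px: int = DEFAULT_FOOTPRINT_RADIUS_PX,
    dims: tuple[int, int] = (600, 960),
) -> ScoreField:
    """Deposit each scored micro frame onto pixels around its tracked position.

    For each score, the associated widefield frame's (valid) tracked tip
    position receives ``sum += score, count += 1`` on every pixel within
    ``footprint_radius_px``. Scores without an association, or whose
    widefield frame has no valid track entry, are skipped.
    """
    h, w = dims
    field_ = ScoreField.zeros((h, w))
    entry_by_idx = {e.frame_index: e for e in track.entries if e.valid}
    offsets = disc_offsets(footprint_radius_px)
    for fs in scores:
        wi = assoc.pairs.get(fs.frame_index)
        if wi is None:
            continue
        entry = entry_by_idx.get(wi)
        if entry is None:
            continue
        px = int(round(entry.x))
        py = int(round(entry.y))
        xs = px + offsets[:, 0]
        ys = py + offsets[:, 1]
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        field_.sum[ys[ok], xs[ok]] += fs.score
        field_.count[ys[ok], xs[ok]] += 1
    return field_


@dataclass(frozen=True)
class GuidanceThresholds:
    """Clinician-set cutoffs: RG ratio threshold and mean-score threshold."""

    tau_rg: float
    tau_mtn: float

    def __post_init__(self) -> None:
        if self.tau_rg < 0:
            raise InputError("tau_rg must be >= 0")
        if not 0.0 <= self.tau_mtn <= 1.0:
            raise InputError("tau_mtn must lie in [0, 1]")


@dataclass
class GuidanceMap:
    mask: np.ndarray
    thresholds: GuidanceThresholds
    provenance: dict = field(default_factory=dict)


def compute_guidance_map(
    risk: RiskMap, score_field: ScoreField, th: GuidanceThresholds
) -> GuidanceMap:
    """Dual-threshold biopsy recommendation map.

    A pixel is recommended iff it is inside the mucosa mask, has at least one
    deposited score, its normalized RG ratio >= ``tau_rg`` and its mean
    score >= ``tau_mtn``. Unvisited tissue is never recommended.
    """
    if risk.rg.shape != score_field.sum.shape:
        raise InputError("risk map and score field dimensions differ")
    rg_ok = threshold_risk(risk, th.tau_rg)
    mean = score_field.mean()
    mean_filled = np.where(np.isfinite(mean), mean, -np.inf)
    mask = rg_ok & score_field.visited & (mean_filled >= th.tau_mtn)
    return GuidanceMap(mask=mask, thresholds=th, provenance={})


def update_thresholds(
    risk: RiskMap, score_field: ScoreField, new_th: GuidanceThresholds
) -> GuidanceMap:
    """Fast interactive threshold update.

    Operates on the cached risk map and score field only (no raw video or
    per-frame data), and is by contract bitwise-identical to
    :func:`compute_guidance_map` at the same thresholds.
    """
    return compute_guidance_map(risk, score_field, new_th)


def project_guidance(
    guidance: GuidanceMap, h: PlanarHomography, projector_dims: tuple[int, int]
) -> np.ndarray:
    """Warp the guidance mask into projector coordinates (width, height)."""
    out_w, out_h = projector_dims
    return warp_binary_mask(h, guidance.mask, out_w, out_h)
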