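"""Session storage: image/video readers and writers, manifests, hashing.

A session directory holds the WL/AF image pair, the two video streams as
PNG frame directories with timestamp CSVs, the mucosa outline polygon and
a ``manifest.json`` tying them together. All formats are plain text or
standard images so a session round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .exceptions import InputError
from .phantom import SessionData
from .riskmap import RiskMap, MucosaMask, WidefieldFrame
from .scoring import MicroFrame

__all__ = [
    "SessionManifest",
    "write_session",
    "load_manifest",
    "load_widefield_frames",
    "load_micro_frames",
    "read_outline",
    "write_outline",
    "save_risk_map",
    "load_risk_map",
    "save_mask_png",
    "load_mask_png",
    "downsample_widefield",
    "file_sha256",
]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def load_mask_png(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def write_outline(vertices: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"vertices": np.asarray(vertices, float).tolist()}))


def read_outline(path: str | Path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    return np.asarray(data["vertices"], dtype=float)


def save_risk_map(risk: RiskMap, path_tif: str | Path, path_json: str | Path) -> None:
    tifffile.imwrite(Path(path_tif), risk.rg.astype(np.float32))
    Path(path_json).write_text(
        json.dumps(
            {
                "normalization_constant": risk.normalization_constant,
                "epsilon": risk.epsilon,
                "norm_stat": risk.norm_stat,
            }
        )
    )


def load_risk_map(path_tif: str | Path, path_json: str | Path) -> RiskMap:
    rg = tifffile.imread(Path(path_tif)).astype(float)
    meta = json.loads(Path(path_json).read_text())
    mask = MucosaMask(mask=np.isfinite(rg))
    return RiskMap(
        rg=rg,
        mask=mask,
        normalization_constant=meta["normalization_constant"],
        epsilon=meta["epsilon"],
        norm_stat=meta["norm_stat"],
    )


@dataclass
class SessionManifest:
    """Paths and provenance of one acquired (or simulated) session."""

    root: Path
    wl_image: Path
    af_image: Path
    outline: Path
    widefield_dir: Path
    widefield_timestamps: Path
    micro_dir: Path
    micro_timestamps: Path
    seed: int = 0
    fov_center: tuple[float, float] | None = None
    fov_radius: float | None = None
    extra: dict | None = None

    def validate(self) -> None:
        for name in (
            "af_image",
            "outline",
            "widefield_dir",
            "widefield_timestamps",
            "micro_dir",
            "micro_timestamps",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise InputError(f"manifest refers to missing {name}: {p}")


def load_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    data = json.loads(path.read_text())
    root = path.parent
    paths = data["paths"]
    fov = data.get("fov", {})
    return SessionManifest(
        root=root,
        wl_image=root / paths["wl_image"],
        af_image=root / paths["af_image"],
        outline=root / paths["outline"],
        widefield_dir=root / paths["widefield_dir"],
        widefield_timestamps=root / paths["widefield_timestamps"],
        micro_dir=root / paths["micro_dir"],
        micro_timestamps=root / paths["micro_timestamps"],
        seed=int(data.get("seed", 0)),
        fov_center=tuple(fov["center"]) if "center" in fov else None,
        fov_radius=fov.get("radius"),
        extra=data.get("extra"),
    )


def default_outline(width: int, height: int, margin: int = 10) -> np.ndarray:
    """Inset rectangle used as the mucosa outline for simulated sessions."""
    return np.array(
        [
            [margin, margin],
            [width - 1 - margin, margin],
            [width - 1 - margin, height - 1 - margin],
            [margin, height - 1 - margin],
        ],
        dtype=float,
    )


def write_session(session: SessionData, out_dir: str | Path) -> Path:
    """Write a simulated session to disk in the standard layout."""
    out = Path(out_dir)
    (out / "widefield").mkdir(parents=True, exist_ok=True)
    (out / "micro").mkdir(exist_ok=True)

    iio.imwrite(out / "wl.png", session.wl.pixels.astype(np.uint8))
    iio.imwrite(out / "af.png", session.af.pixels.astype(np.uint8))
    save_mask_png(session.lesion_mask, out / "lesion_mask.png")
    w, h = session.spec.widefield_dims
    write_outline(default_outline(w, h), out / "outline.json")

    for frame in session.widefield_frames:
        iio.imwrite(out / "widefield" / f"{frame.frame_index:05d}.png",
                    frame.pixels.astype(np.uint8))
    pd.DataFrame(
        {
            "frame_index": [f.frame_index for f in session.widefield_frames],
            "timestamp_s": [f.timestamp for f in session.widefield_frames],
        }
    ).to_csv(out / "widefield_timestamps.csv", index=False)

    for frame in session.micro_frames:
        iio.imwrite(out / "micro" / f"{frame.frame_index:05d}.png",
                    frame.pixels.astype(np.uint8))
    pd.DataFrame(
        {
            "frame_index": [f.frame_index for f in session.micro_frames],
            "timestamp_s": [f.timestamp for f in session.micro_frames],
        }
    ).to_csv(out / "micro_timestamps.csv", index=False)

    session.truth.true_track.to_csv(out / "truth_track.csv")
    pd.DataFrame(
        {
            "frame_index": list(range(len(session.truth.regime_labels))),
            "regime": session.truth.regime_labels,
        }
    ).to_csv(out / "truth_labels.csv", index=False)

    spec = session.spec
    manifest = {
        "seed": spec.seed,
        "paths": {
            "wl_image": "wl.png",
            "af_image": "af.png",
            "outline": "outline.json",
            "widefield_dir": "widefield",
            "widefield_timestamps": "widefield_timestamps.csv",
            "micro_dir": "micro",
            "micro_timestamps": "micro_timestamps.csv",
        },
        "fov": {
            "center": [spec.micro_dims[0] / 2.0, spec.micro_dims[1] / 2.0],
            "radius": spec.fov_radius_px,
        },
        "extra": {"generator": session.manifest},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _load_timestamps(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"frame_index", "timestamp_s"} <= set(df.columns):
        raise InputError(f"{path} must have frame_index and timestamp_s columns")
    return df


def load_widefield_frames(
    frames_dir: str | Path, timestamps_csv: str | Path, modality: str = "WL"
) -> list[WidefieldFrame]:
    df = _load_timestamps(Path(timestamps_csv))
    frames = []
    for r in df.itertuples():
        img = iio.imread(Path(frames_dir) / f"{int(r.frame_index):05d}.png")
        frames.append(
            WidefieldFrame(
                pixels=img, timestamp=float(r.timestamp_s),
                modality=modality, frame_index=int(r.frame_index),
            )
        )
    return frames


def load_micro_frames(
    frames_dir: str | Path,
    timestamps_csv: str | Path,
    fov_center: tuple[float, float] | None = None,
    fov_radius: float | None = None,
) -> list[MicroFrame]:
    df = _load_timestamps(Path(timestamps_csv))
    frames = []
    for r in df.itertuples():
        img = iio.imread(Path(frames_dir) / f"{int(r.frame_index):05d}.png")
        kwargs = {}
        if fov_radius is not None:
            kwargs["fov_radius"] = fov_radius
        frames.append(
            MicroFrame(
                pixels=img, timestamp=float(r.timestamp_s),
                frame_index=int(r.frame_index), fov_center=fov_center, **kwargs,
            )
        )
    return frames


def downsample_widefield(frame: WidefieldFrame, factor: int) -> WidefieldFrame:
    """Block-mean downsampling by an integer factor (anti-aliased).

    The full-resolution sensor frame (e.g. 1920x1200) is reduced to the
    multimodal-imaging resolution (960x600 at factor 2). Dimensions must be
    divisible by the factor; total intensity times factor^2 is conserved.
    """
    if factor < 1 or int(factor) != factor:
        raise InputError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return frame
    h, w = frame.shape
    if h % factor or w % factor:
        raise InputError(f"frame dims {w}x{h} not divisible by factor {factor}")
    px = frame.pixels.astype(np.float64)
    out = px.reshape(h // factor, factor, w // factor, factor, 3).mean(axis=(1, 3))
    return WidefieldFrame(
        pixels=out.astype(np.float32),
        timestamp=frame.timestamp,
        modality=frame.modality,
        frame_index=frame.frame_index,
    )
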