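"""Reading movies and serializing features, fits, and tracks.

Movies are multi-page TIFF interpreted as ``(T, Z, Y, X)`` or a single
``(Z, Y, X)`` frame (auto-detected from dimensionality, overridable).
Features and composite models serialize to JSON with explicit µm units;
tracks serialize to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .features import CompositeModel, ImageStack
from .track import Track, feature_anchor

__all__ = [
    "read_movie",
    "write_stack",
    "write_movie",
    "save_model_json",
    "load_model_json",
    "save_frame_models",
    "load_frame_models",
    "tracks_to_dataframe",
]


def read_movie(
    path: str | Path,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.5),
    axes: str | None = None,
) -> list[ImageStack]:
    """Read a TIFF movie into per-frame stacks.

    3D data is one frame ``(Z, Y, X)``; 4D is ``(T, Z, Y, X)``.  ``axes``
    may force ``"ZYX"`` or ``"TZYX"`` when the heuristic is wrong.
    """
    try:
        data = tifffile.imread(str(path))
    except (FileNotFoundError, ValueError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read TIFF movie {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise InputError(f"empty TIFF movie {path}")
    if axes == "ZYX" or (axes is None and data.ndim == 3):
        frames = [data]
    elif axes == "TZYX" or (axes is None and data.ndim == 4):
        frames = list(data)
    elif data.ndim == 2:
        frames = [data[None, :, :]]
    else:
        raise InputError(f"unsupported TIFF dimensionality {data.shape}")
    return [ImageStack(np.asarray(f, dtype=float), voxel_size) for f in frames]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(str(path), stack.intensities.astype(np.float32))


def write_movie(path: str | Path, stacks: list[ImageStack]) -> None:
    data = np.stack([s.intensities for s in stacks]).astype(np.float32)
    tifffile.imwrite(str(path), data)


def save_model_json(path: str | Path, model: CompositeModel, meta: dict | None = None) -> None:
    payload = {"model": model.to_dict()}
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model_json(path: str | Path) -> CompositeModel:
    payload = json.loads(Path(path).read_text())
    return CompositeModel.from_dict(payload["model"])


def save_frame_models(
    path: str | Path, models: list[CompositeModel], meta: dict | None = None
) -> None:
    payload = {"frames": [m.to_dict() for m in models]}
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1))


def load_frame_models(path: str | Path) -> list[CompositeModel]:
    payload = json.loads(Path(path).read_text())
    return [CompositeModel.from_dict(d) for d in payload["frames"]]


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to one row per (track, frame) observation."""
    rows = []
    for tr in tracks:
        for frame, feat in tr.items:
            tip = feature_anchor(feat)
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": frame,
                    "time_s": frame * tr.frame_interval,
                    "type": type(feat).__name__.replace("Feature", "").lower(),
                    "length_um": getattr(feat, "length", 0.0),
                    "tip_x": tip[0],
                    "tip_y": tip[1],
                    "tip_z": tip[2],
                    "amplitude": feat.amplitude,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "frame", "time_s", "type", "length_um",
            "tip_x", "tip_y", "tip_z", "amplitude",
        ],
    )
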