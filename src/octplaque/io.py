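"""Readers and writers for the package's on-disk formats.

Mask stacks travel as multi-page TIFF (one page per frame, uint8
labels) with a JSON sidecar carrying the calibration, the lesion span
and the per-frame vulnerable-plaque flags.  Feature tables are UTF-8
CSV with the canonical column names; analysis reports are JSON (sorted
keys, so identical analyses produce byte-identical files); the en-face
(θ, z) fibrous-cap class map exports as an indexed PNG.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .features import FcClassScheme, FEATURE_NAMES
from .geometry import (
    VP_FLAG_NAMES,
    Calibration,
    FrameSegmentation,
    PullbackSegmentation,
    cast_rays,
)

__all__ = [
    "write_pullback",
    "read_pullback",
    "write_feature_table",
    "read_feature_table",
    "write_report",
    "enface_class_map",
    "write_enface_png",
]

_SIDECAR_SUFFIX = ".json"

# indexed-PNG palette: 0 none, 1/2/3 the FC thickness classes
_ENFACE_PALETTE = [0, 0, 0, 0, 170, 0, 80, 180, 255, 220, 40, 40]


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(_SIDECAR_SUFFIX)


def write_pullback(pullback: PullbackSegmentation, tiff_path: str | Path) -> None:
    """Write a mask stack as multi-page TIFF + JSON calibration sidecar."""
    tiff_path = Path(tiff_path)
    stack = np.stack([f.label_mask.astype(np.uint8) for f in pullback.frames])
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    meta = {
        "pixel_size_mm": pullback.calibration.pixel_size,
        "frame_pitch_mm": pullback.calibration.frame_pitch,
        "lesion_span": list(pullback.lesion_span),
        "vp_flags": [
            {k: bool(f.vp_flags[k]) for k in VP_FLAG_NAMES} for f in pullback.frames
        ],
    }
    sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_pullback(tiff_path: str | Path) -> PullbackSegmentation:
    """Read a mask stack written by :func:`write_pullback`.

    Raises a descriptive error on a missing or malformed sidecar or on
    labels outside 0..4.
    """
    tiff_path = Path(tiff_path)
    sc = sidecar_path(tiff_path)
    if not sc.exists():
        raise FileNotFoundError(f"calibration sidecar not found: {sc}")
    try:
        meta = json.loads(sc.read_text())
        cal = Calibration(
            pixel_size=float(meta["pixel_size_mm"]),
            frame_pitch=float(meta["frame_pitch_mm"]),
        )
        span = tuple(int(v) for v in meta["lesion_span"])
        vp = meta.get("vp_flags")
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"corrupt sidecar {sc}: {exc}") from exc
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    frames = []
    for i, page in enumerate(stack):
        flags = (
            {k: bool(vp[i][k]) for k in VP_FLAG_NAMES}
            if vp
            else {k: False for k in VP_FLAG_NAMES}
        )
        frames.append(FrameSegmentation(label_mask=page, vp_flags=flags))
    return PullbackSegmentation(frames=frames, calibration=cal, lesion_span=span)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("Infinity" if obj > 0 else "-Infinity")
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis report to JSON, deterministically."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True) + "\n"
    )


def enface_class_map(
    pullback: PullbackSegmentation,
    n_rays: int = 360,
    scheme: FcClassScheme | None = None,
) -> np.ndarray:
    """En-face (θ, z) map of FC thickness class over the lesion span.

    Rows are frames (z), columns angles; entries 0 (no cap) or the
    class 1/2/3 of the cap on that ray.
    """
    scheme = scheme or FcClassScheme()
    rows = []
    for frame in pullback.lesion_frames():
        profile = cast_rays(frame, pullback.calibration, n_rays=n_rays)
        rows.append(scheme.classify(profile.fc_thickness))
    return np.asarray(rows, dtype=np.uint8)


def write_enface_png(class_map: np.ndarray, path: str | Path) -> None:
    img = Image.fromarray(class_map.astype(np.uint8), mode="P")
    img.putpalette(_ENFACE_PALETTE)
    img.save(path)
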