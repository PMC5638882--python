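"""File formats and run configuration.

Frame stacks travel as multi-page grayscale TIFF with a JSON sidecar
(``<stack>.json``) carrying the instrument parameters, timestamps and any
ground-truth poses; localization results are written as CSV with a fixed,
versioned column order plus a JSON summary.  All lengths in outputs are nm
(d stays in px, as measured on the camera); unmeasured values serialize as
empty fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .instrument import FrameStack, InstrumentModel
from .localize import Localization5D

__all__ = [
    "read_stack",
    "write_stack",
    "write_results",
    "read_results",
    "load_config",
    "instrument_from_config",
    "config_hash",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["frame", "t", "x_nm", "y_nm", "d_px", "z_nm", "score", "flags"]
RESULT_SCHEMA_VERSION = 1

CONFIG_SCHEMA = {
    "instrument": set(InstrumentModel.__dataclass_fields__),
    "thresholds": {"correlation", "mode_hi", "mode_lo", "quiet_frac", "min_quiet_s"},
    "feedback": None,  # scalar: continuous | every:<sec> | off
    "seed": None,
    "paths": {"stack", "calibration", "results"},
}


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(
    stack: FrameStack, path: str | Path, dtype: str = "float32"
) -> Path:
    """Write a frame stack to multi-page TIFF plus a JSON sidecar.

    ``dtype="float32"`` (default) keeps counts lossless; ``"uint16"``
    rounds and clips to the camera's integer range.
    """
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = stack.frames.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "mode": stack.mode,
        "pixel_size": stack.pixel_size,
        "timestamps": stack.timestamps.tolist(),
        "meta": _jsonable(stack.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_stack(path: str | Path, default_pixel_size: float = 160.0) -> FrameStack:
    """Read a multi-page grayscale TIFF (8/16-bit or float) into a FrameStack.

    A JSON sidecar next to the file is merged when present; without one the
    stack is tagged full-plane with a warned default pixel size.  RGB data
    is rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if any(page.samplesperpixel > 1 for page in tif.pages):
            raise ValueError("grayscale required (RGB TIFF given)")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError("expected a (pages, rows, cols) grayscale stack")
    sidecar = _sidecar_path(path)
    mode, pixel_size, timestamps, meta = "fullplane", None, None, {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        mode = info.get("mode", mode)
        pixel_size = info.get("pixel_size")
        timestamps = info.get("timestamps")
        meta = info.get("meta", {})
    if pixel_size is None:
        logger.warning(
            "no pixel size metadata for %s; defaulting to %g nm/px",
            path,
            default_pixel_size,
        )
        pixel_size = default_pixel_size
    if timestamps is None:
        timestamps = np.arange(len(frames), dtype=float)
    return FrameStack(
        frames=np.asarray(frames, dtype=float),
        mode=mode,
        timestamps=np.asarray(timestamps, dtype=float),
        pixel_size=float(pixel_size),
        meta=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(
    records: list[Localization5D], path: str | Path, summary: dict | None = None
) -> Path:
    """Write localization records to CSV (fixed column order) + JSON summary.

    Deterministic: identical records produce byte-identical CSV.  NaN values
    (e.g. z on frames without an axial measurement) serialize as empty
    fields.
    """
    path = Path(path)
    rows = [
        {
            "frame": i,
            "t": rec.t,
            "x_nm": rec.x,
            "y_nm": rec.y,
            "d_px": rec.d,
            "z_nm": rec.z,
            "score": rec.score,
            "flags": ";".join(rec.flags),
        }
        for i, rec in enumerate(records)
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")
    info = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "n_frames": len(records),
        "n_failed": sum(1 for r in records if not r.ok),
    }
    if summary:
        info.update(_jsonable(summary))
    path.with_suffix(".summary.json").write_text(json.dumps(info, sort_keys=True))
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration.

    Unknown top-level sections or unknown keys inside a known section are
    rejected so typos cannot silently fall back to defaults.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for key, val in cfg.items():
        if key not in CONFIG_SCHEMA:
            raise ValueError(f"unknown config section {key!r}")
        allowed = CONFIG_SCHEMA[key]
        if allowed is not None:
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            unknown = set(val) - allowed
            if unknown:
                raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
    return cfg


def instrument_from_config(cfg: dict) -> InstrumentModel:
    params = dict(cfg.get("instrument", {}))
    if "shear" in params:
        params["shear"] = tuple(params["shear"])
    return InstrumentModel(**params)


def config_hash(cfg: dict) -> str:
    """Short stable hash of a configuration, for run logs."""
    blob = json.dumps(_jsonable(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
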