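"""File formats: TIFF images/stacks, CSV spot tables, JSON/YAML configs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import SpotRecord
from .frames import ImageFrame, ImageStack

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "write_spot_table",
    "read_spot_table",
    "RunConfig",
    "load_config",
    "save_config",
    "write_provenance",
]

SPOT_COLUMNS = [
    "cell_id",
    "frame",
    "z_index",
    "x_px",
    "y_px",
    "amplitude",
    "background",
    "score_db",
    "round",
]


class FormatError(ValueError):
    """Unreadable or unsupported image/table format."""


def read_image(path: str | Path, axis: str = "z") -> ImageFrame | ImageStack:
    """Read a single- or multi-page grayscale TIFF (8- or 16-bit).

    A one-page file returns an :class:`ImageFrame`; multi-page files
    return an :class:`ImageStack` along ``axis`` ("z" or "time").
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types on bad files
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        raise FormatError(f"{path} looks like an RGB image; grayscale required")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}; need uint8/uint16")
    if arr.ndim == 2:
        return ImageFrame(pixels=arr, bit_depth=depth)
    if arr.ndim == 3:
        frames = [
            ImageFrame(pixels=a, z_index=(i if axis == "z" else 0),
                       time_s=(float(i) if axis == "time" else 0.0), bit_depth=depth)
            for i, a in enumerate(arr)
        ]
        return ImageStack(frames=frames, axis=axis)
    raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


def write_image(obj: ImageFrame | ImageStack, path: str | Path) -> None:
    """Write a frame or stack as (multi-page) TIFF, preserving bit depth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ImageFrame):
        data = obj.pixels
        depth = obj.bit_depth
    else:
        data = obj.as_array()
        depth = obj.frames[0].bit_depth
    dtype = np.uint8 if depth == 8 else np.uint16
    tifffile.imwrite(path, np.asarray(data, dtype=dtype))


def write_spot_table(
    spots: list[SpotRecord], path: str | Path, cell_id: str = "", frame: int = 0
) -> None:
    """Spot records as CSV with a fixed schema, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "cell_id": cell_id,
            "frame": frame,
            "z_index": -1 if s.z_index is None else s.z_index,
            "x_px": s.x_sub,
            "y_px": s.y_sub,
            "amplitude": s.amplitude,
            "background": s.background,
            "score_db": s.score_db,
            "round": s.depletion_round,
        }
        for s in spots
    ]
    df = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read a spot table CSV, checking the schema."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Parameters shared by the command-line pipelines.

    Round-trips losslessly through JSON/YAML; unknown keys in a config
    file are rejected.
    """

    seed: int = 0
    output_dir: str = "qdfish_out"
    log_level: str = "INFO"
    # simulation
    preset: str = "qd13"
    n_cells: int = 1
    # detection
    sigma_px: float = 1.2
    window_half: int = 3
    threshold_db: float = 30.0
    calibration_mode: str = "exact"
    link_radius_px: float | None = None
    # sweep
    thresholds_db: list[float] = field(
        default_factory=lambda: [25.0, 27.5, 30.0, 32.5, 35.0]
    )
    # photostability
    times_s: list[float] = field(default_factory=lambda: [0.0, 30.0, 60.0, 120.0, 300.0, 600.0])
    # calibration
    n_molecules: int = 100
    n_frames: int = 200
    step_penalty: float = 10.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_provenance(cfg: RunConfig, path: str | Path, command: str) -> None:
    """Machine-readable record sufficient to re-create a run bit-identically."""
    from datetime import datetime, timezone

    from . import __version__

    rec = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": cfg.to_dict(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rec, indent=2) + "\n")
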