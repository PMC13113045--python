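"""Readers and writers for movies, masks, traces, sweeps and results.

Movies are multi-page grayscale TIFF stacks, one page per frame, with the
physical metadata (frame interval in ms, pixel size in µm) carried in a JSON
sidecar next to the file.  Readers never guess missing physical units: a
stack without a frame interval is rejected, because every downstream time
measurement would silently be in frames instead of milliseconds.

Coordinate conventions (stated once, used everywhere): frame index is
0-based; pixels are addressed (row, col) with row 0 at the top; activation
times are reported both in frames and in ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class MetadataError(ValueError):
    """A physical unit (frame interval, pixel size) is missing or invalid."""


@dataclass
class FrameStack:
    """A (time, y, x) fluorescence movie with physical sampling metadata.

    Parameters
    ----------
    frames
        3-D non-negative intensity array ordered (time, y, x).
    frame_interval
        Frame acquisition interval Δt in milliseconds.
    pixel_size
        Pixel edge length in micrometres.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MetadataError(
                f"frames must be (time, y, x); got shape {self.frames.shape}"
            )
        if not self.frame_interval > 0:
            raise MetadataError("frame_interval (ms) must be > 0")
        if not self.pixel_size > 0:
            raise MetadataError("pixel_size (µm) must be > 0")
        if np.nanmin(self.frames) < 0:
            raise MetadataError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def times_ms(self) -> np.ndarray:
        """Frame acquisition times in ms (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration_ms(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class RoiSet:
    """A labelled mask plus an optional label → group-name map.

    Labels are positive integers on a background of 0.  Groups named in
    ``names`` must be non-empty.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")
        for label, name in self.names.items():
            if label <= 0:
                raise ValueError(f"named label {label} ({name!r}) must be positive")
            if not np.any(self.labels == label):
                raise ValueError(f"named group {name!r} (label {label}) has no pixels")

    @property
    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v > 0]

    def mask(self, label: int) -> np.ndarray:
        m = self.labels == label
        if not m.any():
            raise ValueError(f"label {label} has no pixels")
        return m

    def label_for(self, name: str) -> int:
        for label, n in self.names.items():
            if n == name:
                return label
        raise KeyError(f"no group named {name!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path: str | Path, dtype=np.uint16) -> Path:
    """Write a multi-page grayscale TIFF plus a JSON metadata sidecar.

    Intensities are rounded into the target integer dtype; callers that need
    lossless round-trips should generate integer-valued frames.
    """
    path = Path(path)
    frames = np.asarray(stack.frames)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.rint(frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "frame_interval_ms": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
        "n_frames": int(frames.shape[0]),
    }
    write_json(meta, _sidecar_path(path))
    return path


def read_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> FrameStack:
    """Read a multi-page grayscale TIFF into a :class:`FrameStack`.

    Δt and pixel size come from (in order of precedence) explicit arguments,
    then the JSON sidecar.  A stack whose frame interval cannot be
    determined is rejected — never silently defaulted.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 or (frames.ndim == 3 and frames.shape[-1] in (3, 4)
                            and frames.shape[-1] < min(frames.shape[:2])):
        raise MetadataError(
            f"{path} looks like RGB pages; convert to single-channel grayscale first"
        )
    meta: dict = {}
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar.exists():
        meta = read_json(sidecar)
    if frame_interval is None:
        frame_interval = meta.get("frame_interval_ms")
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if frame_interval is None:
        raise MetadataError(
            f"frame interval (ms) for {path} not given and no sidecar value found"
        )
    if pixel_size is None:
        raise MetadataError(
            f"pixel size (µm) for {path} not given and no sidecar value found"
        )
    return FrameStack(frames, float(frame_interval), float(pixel_size))


def write_mask_png(labels: np.ndarray, path: str | Path) -> Path:
    """Write a label mask as a PNG (uint8 or uint16 depending on range)."""
    path = Path(path)
    labels = np.asarray(labels)
    dtype = np.uint8 if labels.max() < 256 else np.uint16
    iio.imwrite(path, labels.astype(dtype))
    return path


def read_mask_png(path: str | Path, names: dict[int, str] | None = None) -> RoiSet:
    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:
        raise MetadataError(f"{path} is not a single-channel label mask")
    return RoiSet(labels.astype(np.int64), names or {})


# ---------------------------------------------------------------------------
# tidy CSV tables


def write_traces_csv(traces: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy trace table (columns: id, time_ms, value)."""
    required = {"id", "time_ms", "value"}
    if not required.issubset(traces.columns):
        raise ValueError(f"trace table needs columns {sorted(required)}")
    path = Path(path)
    traces.to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "time_ms", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} is not a tidy trace table {sorted(required)}")
    return df


def write_sweeps_csv(sweeps: pd.DataFrame, path: str | Path) -> Path:
    """Write a voltage-clamp sweep table (sweep_id, time_ms, command_mV, current_pA)."""
    required = {"sweep_id", "time_ms", "command_mV"}
    if not required.issubset(sweeps.columns):
        raise ValueError(f"sweep table needs columns {sorted(required)}")
    path = Path(path)
    sweeps.to_csv(path, index=False)
    return path


def read_sweeps_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sweep_id" not in df.columns or "time_ms" not in df.columns:
        raise ValueError(f"{path} is not a sweep table")
    return df


# ---------------------------------------------------------------------------
# JSON results


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file (lines starting with # ignored)."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line is not 'key = value': {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
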