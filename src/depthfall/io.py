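"""Reading and writing depth sequences on disk.

A sequence is a directory of 16-bit grayscale PNGs (one per frame, zero-padded
index filenames) plus a ``meta.json`` sidecar.  Depth values are stored
verbatim in millimetres; the value 0 marks an invalid pixel (no measurement).
Timestamps are derived from the fixed frame rate rather than stored.

Dataset layout::

    <root>/<subject_id>/<action_code>/frame_00000.png ... meta.json
    <root>/background_<subject_id>/frame_00000.png ... meta.json
    <root>/manifest.csv   # sequence_dir, subject_id, action_code, label
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import ActionCode, DetectorParams, SequenceLabel

__all__ = [
    "DepthFrame",
    "SequenceMeta",
    "write_sequence",
    "read_sequence",
    "read_labels",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["sequence_dir", "subject_id", "action_code", "label"]


@dataclass
class DepthFrame:
    """One depth frame: a uint16 grid of sensor-to-surface distances (mm)."""

    grid: np.ndarray
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("depth grid must be two-dimensional")
        if self.grid.dtype != np.uint16:
            if np.any(self.grid < 0) or np.any(self.grid >= 2 ** 16):
                raise ValueError("depth values must fit in 16 unsigned bits")
            self.grid = self.grid.astype(np.uint16)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels carrying an actual measurement."""
        return self.grid > 0


@dataclass
class SequenceMeta:
    """Sidecar metadata of one recorded sequence."""

    subject_id: str
    action_code: str
    fps: float
    sensor_height_mm: float
    n_frames: int
    background_ref: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("a sequence holds at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "action_code": self.action_code,
            "fps": self.fps,
            "sensor_height_mm": self.sensor_height_mm,
            "n_frames": self.n_frames,
            "background_ref": self.background_ref,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SequenceMeta":
        return cls(**data)


def _frame_name(index: int) -> str:
    return f"frame_{index:05d}.png"


def write_sequence(frames: list[DepthFrame], meta: SequenceMeta,
                   directory: str | Path) -> Path:
    """Write a depth sequence as 16-bit PNGs plus a ``meta.json`` sidecar."""
    if not frames:
        raise ValueError("cannot write an empty sequence")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(directory / _frame_name(i), frame.grid)
    meta.n_frames = len(frames)
    (directory / "meta.json").write_text(json.dumps(meta.to_dict(), indent=2))
    return directory


def read_sequence(directory: str | Path) -> tuple[list[DepthFrame], SequenceMeta]:
    """Read a sequence directory back; timestamps reconstructed as i / fps."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.json in {directory}")
    meta = SequenceMeta.from_dict(json.loads(meta_path.read_text()))
    paths = sorted(directory.glob("frame_*.png"))
    if len(paths) != meta.n_frames:
        raise ValueError(
            f"{directory}: meta declares {meta.n_frames} frames "
            f"but {len(paths)} PNG files found"
        )
    frames = []
    for i, path in enumerate(paths):
        grid = np.asarray(iio.imread(path))
        if grid.dtype != np.uint16:
            grid = grid.astype(np.uint16)
        frames.append(DepthFrame(grid=grid, timestamp_s=i / meta.fps))
    return frames, meta


def read_labels(csv_path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset manifest.

    Every row's action code must belong to the protocol vocabulary and its
    label must match the code's ground truth.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    for _, row in df.iterrows():
        code = ActionCode.parse(str(row["action_code"]))  # raises on bad codes
        if str(row["label"]) != code.label.value:
            raise ValueError(
                f"manifest row {row['sequence_dir']}: label {row['label']!r} "
                f"inconsistent with action code {code} ({code.label.value})"
            )
    return df


def write_labels(rows: list[dict], csv_path: str | Path) -> Path:
    """Write a manifest CSV with the canonical column order."""
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(csv_path, index=False)
    return Path(csv_path)


def load_dataset(manifest_csv: str | Path):
    """Stream ``(manifest_row, frames, background)`` triples from disk.

    Paths in the manifest are resolved relative to its directory; each
    sequence's background is located through its ``meta.json``
    ``background_ref``.
    """
    manifest_csv = Path(manifest_csv)
    root = manifest_csv.parent
    df = read_labels(manifest_csv)
    bg_cache: dict[str, list[DepthFrame]] = {}
    for _, row in df.iterrows():
        seq_dir = root / str(row["sequence_dir"])
        frames, meta = read_sequence(seq_dir)
        bg_key = meta.background_ref or f"background_{row['subject_id']}"
        if bg_key not in bg_cache:
            bg_frames, _ = read_sequence(root / bg_key)
            bg_cache = {bg_key: bg_frames}  # keep one background at a time
        yield row.to_dict(), frames, bg_cache[bg_key]
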