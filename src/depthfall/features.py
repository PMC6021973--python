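"""Depth Values Histogram (DVH) features.

The DVH of a person blob is the histogram of its depth values, normalised
with respect to the floor distance: each valid depth is mapped to
``v = clamp(depth, 0, sensor_height) / sensor_height`` in [0, 1] and binned
into ``num_bins`` uniform bins (the last bin is right-closed, so the floor
itself lands in the final bin).  Bin weights are divided by the pixel count,
so every DVH sums to one regardless of blob size — which also makes the L1
blob-association threshold scale-free.

An alternative normalisation — height above the floor as a fraction of the
sensor height, ``v = 1 - depth / sensor_height`` — can be selected with
``mode="height_above_floor"``; the default is the distance-from-sensor
fraction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .config import DetectorParams
from .io import DepthFrame

__all__ = ["dvh", "feature_matrix", "augment_rotations"]


def dvh(frame: DepthFrame, blob_mask: np.ndarray, params: DetectorParams,
        mode: str = "distance") -> np.ndarray:
    """Unit-sum depth histogram of a blob (the SVM feature vector)."""
    values = frame.grid[blob_mask]
    values = values[values > 0].astype(np.float64)
    if values.size == 0:
        raise ValueError("cannot compute a DVH on an empty blob")
    v = np.clip(values, 0.0, params.sensor_height_mm) / params.sensor_height_mm
    if mode == "height_above_floor":
        v = 1.0 - v
    elif mode != "distance":
        raise ValueError(f"unknown DVH normalisation mode {mode!r}")
    idx = np.minimum((v * params.num_bins).astype(np.int64), params.num_bins - 1)
    hist = np.bincount(idx, minlength=params.num_bins).astype(np.float64)
    return hist / values.size


def feature_matrix(buffer_frames: Iterable[tuple[DepthFrame, np.ndarray]],
                   params: DetectorParams,
                   mode: str = "distance",
                   ) -> tuple[np.ndarray, list[int]]:
    """DVH matrix (num_bins x n_frames) over a buffered frame window.

    Frames whose mask is empty (no person) are skipped; their indices are
    returned alongside the matrix.  Raises if no frame is retained.
    """
    columns: list[np.ndarray] = []
    skipped: list[int] = []
    for j, (frame, mask) in enumerate(buffer_frames):
        if mask is None or not np.any(mask & frame.valid_mask):
            skipped.append(j)
            continue
        columns.append(dvh(frame, mask, params, mode=mode))
    if not columns:
        raise ValueError("no frames with a person blob in the buffer")
    return np.column_stack(columns), skipped


def augment_rotations(frames_with_masks: Sequence[tuple[DepthFrame, np.ndarray]],
                      angles: Sequence[int] = (90, 180, 270),
                      ) -> list[tuple[DepthFrame, np.ndarray]]:
    """Append right-angle-rotated replicas of each (frame, mask) pair.

    Originals come first, in order; rotations are exact pixel permutations
    (``np.rot90``), so any feature that depends only on the depth multiset —
    the DVH in particular — is unchanged by them.  Non-right angles would
    require interpolation and are rejected.
    """
    for angle in angles:
        if angle % 90 != 0:
            raise ValueError(
                f"rotation by {angle} deg needs interpolation; only right "
                "angles are supported"
            )
    out = list(frames_with_masks)
    for angle in angles:
        quarter = (angle // 90) % 4
        for frame, mask in frames_with_masks:
            grid = np.rot90(frame.grid, k=quarter).copy()
            rmask = np.rot90(mask, k=quarter).copy()
            out.append((DepthFrame(grid=grid, timestamp_s=frame.timestamp_s),
                        rmask))
    return out
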