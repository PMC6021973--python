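"""Person-blob segmentation from top-view depth frames.

The scene background (floor plus furniture) is modelled as a per-pixel median
of a person-free depth sequence.  Foreground pixels are those measurably
nearer to the sensor than the background; 8-connected components above a
minimum area become candidate blobs.  The person is recognised among blobs by
anthropometric gates (area range, minimum height above the floor), and the
head distance ``act_dist`` — sensor-to-head distance in the current frame —
is estimated robustly as the mean of the k smallest valid depths in the blob.

Zero-valued pixels mean "no measurement" and never enter medians, histograms
or minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .config import DetectorParams, threshold_fall
from .io import DepthFrame

__all__ = [
    "BackgroundModel",
    "PersonBlob",
    "TrackedPerson",
    "AnthropometricGates",
    "build_background",
    "extract_foreground",
    "find_blobs",
    "head_distance",
    "identify_person",
    "enroll_pers_dist",
]

#: Default background-subtraction margin: a pixel is foreground when it is at
#: least this much nearer to the sensor than the background (mm).
DEFAULT_DELTA_MM = 80.0

#: Default connected-component minimum area (pixels) — drops depth speckle.
DEFAULT_MIN_AREA_PX = 150

#: Head estimator: number of smallest depths averaged.
DEFAULT_HEAD_K = 25

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class BackgroundModel:
    """Per-pixel median depth of the empty scene, with a validity mask."""

    median_mm: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.median_mm.shape


@dataclass
class PersonBlob:
    """A segmented foreground component."""

    mask: np.ndarray          # boolean pixel mask, frame-shaped
    area_px: int
    act_dist_mm: float        # sensor-to-head distance in this frame
    bounding_box: tuple[int, int, int, int]   # (row0, col0, row1, col1), half-open
    dvh: Optional[np.ndarray] = None          # unit-sum depth histogram, lazy

    def overlap(self, other: "PersonBlob") -> int:
        return int(np.count_nonzero(self.mask & other.mask))


@dataclass
class TrackedPerson:
    """Tracking record of the (single) person in the scene."""

    pers_dist_mm: float       # standing reference distance, set at enrolment
    first_seen_frame: int
    last_blob: Optional[PersonBlob] = None


@dataclass(frozen=True)
class AnthropometricGates:
    """Acceptance gates used when (re-)acquiring the person among blobs."""

    min_area_px: int = 400
    max_area_px: int = 8000
    min_height_above_floor_mm: float = 300.0


def build_background(background_frames: Sequence[DepthFrame]) -> BackgroundModel:
    """Per-pixel median over valid (non-zero) background samples."""
    if len(background_frames) == 0:
        raise ValueError("background model needs at least one frame")
    stack = np.stack([f.grid for f in background_frames]).astype(np.float64)
    stack[stack == 0] = np.nan
    with np.errstate(all="ignore"):
        median = np.nanmedian(stack, axis=0)
    valid = ~np.isnan(median)
    median = np.where(valid, median, 0.0)
    return BackgroundModel(median_mm=median, valid=valid)


def extract_foreground(frame: DepthFrame, bg: BackgroundModel,
                       delta_mm: float = DEFAULT_DELTA_MM) -> np.ndarray:
    """Pixels strictly nearer to the sensor than the background by delta_mm."""
    if frame.grid.shape != bg.shape:
        raise ValueError(
            f"frame shape {frame.grid.shape} does not match background {bg.shape}"
        )
    depth = frame.grid.astype(np.float64)
    return (frame.valid_mask & bg.valid
            & (bg.median_mm - depth > delta_mm))


def head_distance(blob_mask: np.ndarray, frame: DepthFrame,
                  k: int = DEFAULT_HEAD_K) -> float:
    """Sensor-to-head estimate: mean of the k smallest valid blob depths.

    Averaging over the highest body part (head cap in a top view) rather than
    taking the single minimum makes the estimate robust to depth noise; k is
    clipped to the number of valid pixels.
    """
    values = frame.grid[blob_mask]
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("blob has no valid depth measurements")
    k = min(k, values.size)
    smallest = np.partition(values.astype(np.float64), k - 1)[:k]
    return float(smallest.mean())


def find_blobs(mask: np.ndarray, frame: DepthFrame,
               min_area_px: int = DEFAULT_MIN_AREA_PX,
               head_k: int = DEFAULT_HEAD_K) -> list[PersonBlob]:
    """8-connected foreground components at or above the minimum area."""
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    blobs: list[PersonBlob] = []
    if n == 0:
        return blobs
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        component = labels[sl] == i
        area = int(component.sum())
        if area < min_area_px:
            continue
        full = np.zeros_like(mask)
        full[sl] = component
        try:
            act = head_distance(full, frame, k=head_k)
        except ValueError:
            continue  # component has only invalid pixels
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        blobs.append(PersonBlob(mask=full, area_px=area, act_dist_mm=act,
                                bounding_box=(r0, c0, r1, c1)))
    return blobs


def identify_person(blobs: list[PersonBlob], params: DetectorParams,
                    gates: AnthropometricGates = AnthropometricGates(),
                    ) -> Optional[PersonBlob]:
    """Pick the person among candidate blobs by anthropometric gates.

    A candidate must have an area in the configured range and a head at least
    ``min_height_above_floor_mm`` above the floor.  Ties are broken by the
    largest area.  Used for initial acquisition; once tracked, the person is
    followed by blob overlap instead (a lying person fails the height gate).
    """
    candidates = []
    for blob in blobs:
        if not gates.min_area_px <= blob.area_px <= gates.max_area_px:
            continue
        height_above_floor = params.sensor_height_mm - blob.act_dist_mm
        if height_above_floor < gates.min_height_above_floor_mm:
            continue
        candidates.append(blob)
    if not candidates:
        return None
    return max(candidates, key=lambda b: b.area_px)


def enroll_pers_dist(act_dists: Sequence[float], params: DetectorParams) -> float:
    """Standing reference distance from the first person observations.

    The median of the first qualifying head distances.  Enrolment is refused
    when the very first observation is already at or past the near-floor
    threshold — the person entered the scene falling, and no upright
    reference can be established.
    """
    if len(act_dists) == 0:
        raise ValueError("no head-distance observations to enrol from")
    th = threshold_fall(params)
    if act_dists[0] >= th:
        raise ValueError(
            "enrolment refused: first observation already below the "
            "near-floor threshold (person entered the scene falling)"
        )
    qualifying = [d for d in act_dists if d < th]
    return float(np.median(qualifying))
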