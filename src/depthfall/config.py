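"""Detector parameters, the acquisition protocol vocabulary, and subject data.

All thresholds of the fall detector live in a single immutable
:class:`DetectorParams` record that is threaded explicitly through every
module.  The defaults are the empirical configuration of the ceiling-mounted
sensor study this package implements: a depth sensor 3 m above the floor,
320x240 depth frames at 30 fps, and a handful of temporal windows (in
seconds) that separate falls, warnings (falls followed by recovery) and
activities of daily living (ADLs).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from enum import Enum
from typing import Iterable

import yaml

__all__ = [
    "DetectorParams",
    "ActionCode",
    "SequenceLabel",
    "SubjectProfile",
    "FALL_PREFIXES",
    "ADL_PREFIXES",
    "FALL_SUFFIXES",
    "ADL_SUFFIXES",
    "SUBJECTS",
    "threshold_fall",
    "th_var",
    "protocol_catalog",
]


@dataclass(frozen=True)
class DetectorParams:
    """Complete parameter set of the fall detector.

    Lengths are millimetres, durations seconds.  ``th_var_fraction`` is the
    15% factor used to derive the per-person height-variation tolerance
    ``th_var`` from the standing reference distance.
    """

    sensor_height_mm: float = 3000.0
    floor_distance_mm: float = 600.0
    wind_time_s: float = 3.0
    recovery_time_s: float = 2.0
    warning_time_s: float = 1.0
    sit_time_s: float = 3.0
    shift_time_s: float = 1.0
    wait_time_s: float = 1.0
    num_bins: int = 256
    fps: float = 30.0
    th_var_fraction: float = 0.15
    frame_width: int = 320
    frame_height: int = 240

    def __post_init__(self) -> None:
        positive = (
            "sensor_height_mm",
            "floor_distance_mm",
            "wind_time_s",
            "recovery_time_s",
            "warning_time_s",
            "sit_time_s",
            "shift_time_s",
            "wait_time_s",
            "num_bins",
            "fps",
            "frame_width",
            "frame_height",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.th_var_fraction < 1.0:
            raise ValueError("th_var_fraction must lie in (0, 1)")
        if not self.warning_time_s < self.recovery_time_s:
            raise ValueError(
                "warning_time_s must be smaller than recovery_time_s "
                "(a Warning must be able to precede a Fall)"
            )
        if not self.floor_distance_mm < self.sensor_height_mm:
            raise ValueError("floor_distance_mm must be below sensor_height_mm")

    # -- config file round trip ------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorParams":
        """Load parameters from a YAML or JSON file; unknown keys rejected."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "DetectorParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        data = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    # -- derived quantities ----------------------------------------------

    @property
    def buffer_capacity(self) -> int:
        """Maximum number of frames held in the depth-frame buffer."""
        return int(round((self.sit_time_s + self.shift_time_s) * self.fps)) + 1


def threshold_fall(params: DetectorParams) -> float:
    """Near-floor distance threshold: sensor height minus floor clearance.

    A head distance (sensor to head) strictly greater than this value means
    the person is within ``floor_distance_mm`` of the floor.
    """
    return params.sensor_height_mm - params.floor_distance_mm


def th_var(params: DetectorParams, pers_dist_mm: float) -> float:
    """Height-variation tolerance: a fixed fraction of the standing height.

    ``pers_dist_mm`` is the sensor-to-head distance recorded while the person
    stands upright; the tolerance scales with the person's height above the
    sensor-to-floor baseline, so taller subjects get a wider recovery band.
    """
    if pers_dist_mm >= params.sensor_height_mm:
        raise ValueError("pers_dist must be smaller than the sensor height")
    if pers_dist_mm <= 0:
        raise ValueError("pers_dist must be positive")
    return params.th_var_fraction * (params.sensor_height_mm - pers_dist_mm)


# ---------------------------------------------------------------------------
# Acquisition protocol vocabulary
# ---------------------------------------------------------------------------

#: Fall action families: direction / final posture of the simulated fall.
FALL_PREFIXES = (
    "FBELFR",  # backward fall finishing lying
    "FBESFR",  # backward fall finishing sitting on the ground
    "FFELFR",  # forward fall finishing lying
    "FFOKCH",  # forward fall on the knees grabbing the chair
    "FFOKFR",  # forward fall on the knees
    "FFOKSO",  # forward fall on the knees grabbing the sofa
    "FSLEFR",  # left-side fall finishing lying
    "FSRIFR",  # right-side fall finishing lying
)

#: ADL action families: everyday movements that must not raise alarms.
ADL_PREFIXES = (
    "APBE",  # pick up an object bending
    "APSQ",  # pick up an object squatting
    "ASCH",  # sit on and rise from a chair
    "ASSO",  # sit on and rise from a couch
)

#: Fall variants: from standing / walking, with or without recovery (RC).
FALL_SUFFIXES = ("ST", "STRC", "WK", "WKRC")

#: ADL variants: started from standing or from walking.
ADL_SUFFIXES = ("ST", "WK")


class SequenceLabel(str, Enum):
    """Ground-truth class of a recorded sequence."""

    ADL = "ADL"
    FALL = "Fall"
    WARNING = "Warning"


@dataclass(frozen=True)
class ActionCode:
    """One of the 40 scripted actions of the acquisition protocol."""

    prefix: str
    suffix: str

    def __post_init__(self) -> None:
        if self.prefix in FALL_PREFIXES:
            if self.suffix not in FALL_SUFFIXES:
                raise ValueError(
                    f"fall action {self.prefix} admits suffixes {FALL_SUFFIXES}, "
                    f"got {self.suffix!r}"
                )
        elif self.prefix in ADL_PREFIXES:
            if self.suffix not in ADL_SUFFIXES:
                raise ValueError(
                    f"ADL action {self.prefix} admits suffixes {ADL_SUFFIXES}, "
                    f"got {self.suffix!r}"
                )
        else:
            raise ValueError(f"unknown action prefix {self.prefix!r}")

    @property
    def is_fall(self) -> bool:
        return self.prefix in FALL_PREFIXES

    @property
    def is_recovery(self) -> bool:
        return self.suffix in ("STRC", "WKRC")

    @property
    def from_walking(self) -> bool:
        return self.suffix in ("WK", "WKRC")

    @property
    def label(self) -> SequenceLabel:
        """Ground-truth sequence label implied by the action script."""
        if not self.is_fall:
            return SequenceLabel.ADL
        return SequenceLabel.WARNING if self.is_recovery else SequenceLabel.FALL

    def __str__(self) -> str:
        return f"{self.prefix}-{self.suffix}"

    @classmethod
    def parse(cls, text: str) -> "ActionCode":
        """Parse ``'FBELFR-STRC'`` or the concatenated form ``'FBELFRSTRC'``."""
        if "-" in text:
            prefix, suffix = text.split("-", 1)
            return cls(prefix, suffix)
        for prefix in FALL_PREFIXES + ADL_PREFIXES:
            if text.startswith(prefix):
                return cls(prefix, text[len(prefix):])
        raise ValueError(f"unrecognised action code {text!r}")


def protocol_catalog() -> list[tuple[ActionCode, SequenceLabel]]:
    """The full 40-action protocol with ground-truth labels.

    32 fall variants (8 families x {ST, STRC, WK, WKRC}) and 8 ADL variants
    (4 families x {ST, WK}).  Recovery variants are labelled Warning, plain
    falls Fall, ADLs ADL.
    """
    catalog: list[tuple[ActionCode, SequenceLabel]] = []
    for prefix in FALL_PREFIXES:
        for suffix in FALL_SUFFIXES:
            code = ActionCode(prefix, suffix)
            catalog.append((code, code.label))
    for prefix in ADL_PREFIXES:
        for suffix in ADL_SUFFIXES:
            code = ActionCode(prefix, suffix)
            catalog.append((code, code.label))
    return catalog


# ---------------------------------------------------------------------------
# Study cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometric record of one test subject."""

    subject_id: str
    sex: str  # "M" or "F"
    age: int
    weight_kg: float
    height_cm: float
    min_height_cm: float = 140.0
    max_height_cm: float = 210.0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not self.min_height_cm <= self.height_cm <= self.max_height_cm:
            raise ValueError(
                f"height {self.height_cm} cm outside plausible range "
                f"[{self.min_height_cm}, {self.max_height_cm}]"
            )

    @property
    def height_mm(self) -> float:
        return self.height_cm * 10.0


def _subjects(rows: Iterable[tuple[str, str, int, float, float]]):
    return tuple(SubjectProfile(*row) for row in rows)


#: The 20-subject cohort of the acquisition campaign (sex, age, weight kg,
#: height cm).  Used as the default anthropometrics of the simulator.
SUBJECTS: tuple[SubjectProfile, ...] = _subjects([
    ("ES01", "M", 28, 65, 177),
    ("ES02", "F", 40, 60, 163),
    ("ES03", "F", 35, 63, 161),
    ("ES04", "F", 29, 74, 170),
    ("ES05", "F", 25, 52, 160),
    ("ES06", "F", 26, 55, 165),
    ("ES07", "M", 30, 65, 176),
    ("ES08", "M", 55, 80, 173),
    ("ES09", "M", 21, 58, 169),
    ("ES10", "M", 21, 70, 178),
    ("ES11", "M", 23, 59, 175),
    ("ES12", "M", 28, 74, 178),
    ("ES13", "M", 28, 76, 160),
    ("ES14", "M", 26, 73, 182),
    ("ES15", "M", 40, 87, 187),
    ("ES16", "M", 21, 80, 189),
    ("ES17", "M", 22, 64, 167),
    ("ES18", "M", 22, 72, 170),
    ("ES19", "M", 21, 78, 188),
    ("ES20", "M", 21, 78, 177),
])
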