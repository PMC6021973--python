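"""Synthetic top-view depth scenes reproducing the acquisition protocol.

Real recordings of the 40-action protocol (20 subjects x 32 falls + 8 ADLs)
were never published, so this module renders protocol-conformant depth
sequences from parametric head-height trajectories: a flat floor 3 m below
the sensor, optional furniture, and a person blob whose footprint and depth
follow the scripted action.  The renderer is deliberately simple — posture-
dependent elliptical footprints with a head cap, an orthographic scale of
10 mm/pixel, per-pixel Gaussian depth noise and a border dropout band — but
it reproduces the quantities the detector actually observes: the head
distance over time and the depth-value distribution of the blob.

Default geometry (all heights above the floor, in mm): lying head 250,
kneeling 600, sitting on the ground 700, chair seat 450, sofa seat 400.
Lying falls therefore cross the near-floor threshold (head distance
> 2400 mm) while knee/sitting falls stop right at it and must be separated
from furniture sitting by the depth-histogram SVM stage — the discrimination
this system exists for.  Falls descend in ~0.7 s; ADL bends and sits take
>= 1.2 s, giving the classifier a distributional signal.

All timings are simulator conventions (the study reports no fall
kinematics); they are chosen so that scripted falls, recoveries and ADLs
land on the intended side of each temporal window with a comfortable margin.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .config import (
    ActionCode,
    DetectorParams,
    SequenceLabel,
    SubjectProfile,
    protocol_catalog,
)
from .io import DepthFrame, SequenceMeta, write_labels, write_sequence

__all__ = [
    "Phase",
    "TrajectorySpec",
    "Furniture",
    "SceneSpec",
    "trajectory_for_action",
    "render_sequence",
    "generate_dataset",
    "dataset_plan",
    "iter_sequences",
    "edge_case_sequences",
    "EDGE_CASE_NAMES",
]

#: Orthographic rendering scale.
MM_PER_PX = 10.0

# -- default scene geometry (mm above the floor) ----------------------------
LYING_HEAD_MM = 250.0
KNEELING_HEAD_MM = 600.0
SITTING_GROUND_HEAD_MM = 700.0
CHAIR_SEAT_MM = 450.0
SOFA_SEAT_MM = 400.0
SITTING_TORSO_FRACTION = 0.48   # seated head height above the seat, x height
BEND_FRACTION = 0.45            # head height while bending, x height
SQUAT_FRACTION = 0.50

# -- default phase durations (s) --------------------------------------------
STAND_BEFORE_S = 1.5
ENTER_S = 1.0
WALK_S = 1.5
FALL_DESCEND_S = 0.7
ON_GROUND_S = 5.0        # non-recovery falls: long enough for every window
ON_GROUND_RC_S = 3.0     # recovery falls: below the 4 s evaluation window
RECOVER_S = 1.2
ADL_DESCEND_S = 1.2
ADL_HOLD_S = 1.0         # bend/squat hold: keeps the episode under 4 s
SIT_HOLD_S = 4.5         # furniture sits exceed 4 s: the SVM must answer ADL
SIT_DESCEND_S = 1.5
STAND_AFTER_S = 1.0

#: Posture-dependent footprint semi-axes (rows, cols) in px at height 176 cm.
_FOOTPRINTS = {
    "upright": (13.0, 18.0),
    "bent": (14.0, 22.0),
    "kneeling": (14.0, 20.0),
    "sitting_ground": (14.0, 18.0),
    "sitting_furniture": (13.0, 16.0),
    "lying": (12.0, 60.0),        # long axis along columns
    "lying_rows": (60.0, 12.0),   # side falls: long axis along rows
}

_HEAD_RADIUS_PX = 9.0


@dataclass(frozen=True)
class Phase:
    """One linearly interpolated segment of a trajectory."""

    name: str                    # enter|walk|stand|descend|on_ground|recover|bend|squat|sit|rise|exit
    duration_s: float
    head_start_mm: float         # head height above the floor
    head_end_mm: float
    posture: str                 # key into the footprint table
    pos_start: tuple[float, float] = (120.0, 160.0)   # (row, col) px
    pos_end: tuple[float, float] = (120.0, 160.0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("phase duration must be positive")
        if self.head_start_mm < 0 or self.head_end_mm < 0:
            raise ValueError("head heights must be non-negative")


@dataclass(frozen=True)
class TrajectorySpec:
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.head_end_mm - b.head_start_mm) > 1e-6:
                raise ValueError(
                    f"trajectory not height-continuous between phases "
                    f"{a.name!r} and {b.name!r}"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)


@dataclass(frozen=True)
class Furniture:
    kind: str                                 # "chair" | "sofa"
    rect: tuple[int, int, int, int]           # (row0, col0, row1, col1)
    top_height_mm: float


def _default_furniture() -> tuple[Furniture, ...]:
    return (
        Furniture("chair", (30, 250, 48, 268), CHAIR_SEAT_MM),
        Furniture("sofa", (180, 40, 215, 100), SOFA_SEAT_MM),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Static scene plus the noise model of the renderer."""

    floor_depth_mm: float = 3000.0
    furniture: tuple[Furniture, ...] = field(default_factory=_default_furniture)
    noise_sigma_mm: float = 10.0
    border_dropout_rate: float = 0.3
    border_px: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.border_dropout_rate <= 1.0:
            raise ValueError("border_dropout_rate must lie in [0, 1]")
        for item in self.furniture:
            if item.top_height_mm >= self.floor_depth_mm:
                raise ValueError("furniture cannot reach the sensor")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_FALL_END = {
    "FBELFR": (LYING_HEAD_MM, "lying"),
    "FFELFR": (LYING_HEAD_MM, "lying"),
    "FSLEFR": (LYING_HEAD_MM, "lying_rows"),
    "FSRIFR": (LYING_HEAD_MM, "lying_rows"),
    "FBESFR": (SITTING_GROUND_HEAD_MM, "sitting_ground"),
    "FFOKCH": (KNEELING_HEAD_MM, "kneeling"),
    "FFOKFR": (KNEELING_HEAD_MM, "kneeling"),
    "FFOKSO": (KNEELING_HEAD_MM, "kneeling"),
}

_CENTER = (120.0, 160.0)
_WALK_START = (120.0, 60.0)
_WALK_END = (120.0, 150.0)
_ENTER_FROM = (120.0, -30.0)


def _jitter(rng: np.random.Generator, value: float, frac: float = 0.05) -> float:
    return float(value * (1.0 + rng.uniform(-frac, frac)))


def trajectory_for_action(code: ActionCode, subject: SubjectProfile,
                          rng_seed: int) -> TrajectorySpec:
    """Scripted head-height trajectory for one protocol action.

    The random seed only jitters phase durations slightly (±5%), emulating
    actor variability without moving any action across a decision window.
    """
    rng = np.random.default_rng(rng_seed)
    H = subject.height_mm
    phases: list[Phase] = []

    def add(name, dur, h0, h1, posture, p0, p1):
        phases.append(Phase(name, dur, h0, h1, posture, p0, p1))

    if code.from_walking:
        add("enter", _jitter(rng, ENTER_S), H, H, "upright",
            _ENTER_FROM, _WALK_START)
        add("walk", _jitter(rng, WALK_S), H, H, "upright",
            _WALK_START, _WALK_END)
        spot = _WALK_END
    else:
        add("stand", _jitter(rng, STAND_BEFORE_S), H, H, "upright",
            _CENTER, _CENTER)
        spot = _CENTER

    if code.is_fall:
        h_end, posture = _FALL_END[code.prefix]
        add("descend", _jitter(rng, FALL_DESCEND_S), H, h_end, posture,
            spot, spot)
        if code.is_recovery:
            add("on_ground", _jitter(rng, ON_GROUND_RC_S, 0.04), h_end, h_end,
                posture, spot, spot)
            add("recover", _jitter(rng, RECOVER_S, 0.04), h_end, H, "upright",
                spot, spot)
            add("stand", _jitter(rng, STAND_AFTER_S), H, H, "upright",
                spot, spot)
        else:
            add("on_ground", _jitter(rng, ON_GROUND_S), h_end, h_end,
                posture, spot, spot)
    else:
        if code.prefix == "APBE":
            h_low, posture, hold_name = BEND_FRACTION * H, "bent", "bend"
            descend, hold = ADL_DESCEND_S, ADL_HOLD_S
        elif code.prefix == "APSQ":
            h_low, posture, hold_name = SQUAT_FRACTION * H, "bent", "squat"
            descend, hold = ADL_DESCEND_S, ADL_HOLD_S
        elif code.prefix == "ASCH":
            h_low = CHAIR_SEAT_MM + SITTING_TORSO_FRACTION * H
            posture, hold_name = "sitting_furniture", "sit"
            descend, hold = SIT_DESCEND_S, SIT_HOLD_S
        else:  # ASSO
            h_low = SOFA_SEAT_MM + SITTING_TORSO_FRACTION * H
            posture, hold_name = "sitting_furniture", "sit"
            descend, hold = SIT_DESCEND_S, SIT_HOLD_S
        add("descend", _jitter(rng, descend, 0.04), H, h_low, posture,
            spot, spot)
        add(hold_name, _jitter(rng, hold, 0.04), h_low, h_low, posture,
            spot, spot)
        add("rise", _jitter(rng, descend, 0.04), h_low, H, "upright",
            spot, spot)
        add("stand", _jitter(rng, STAND_AFTER_S), H, H, "upright",
            spot, spot)

    return TrajectorySpec(phases=tuple(phases))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _scene_base(scene: SceneSpec, params: DetectorParams) -> np.ndarray:
    base = np.full((params.frame_height, params.frame_width),
                   scene.floor_depth_mm, dtype=np.float64)
    for item in scene.furniture:
        r0, c0, r1, c1 = item.rect
        base[r0:r1, c0:c1] = scene.floor_depth_mm - item.top_height_mm
    return base


def _person_layer(canvas: np.ndarray, center: tuple[float, float],
                  head_height_mm: float, posture: str, subject_scale: float,
                  floor_depth_mm: float) -> None:
    """Paint the person into ``canvas`` (depth mm, in place)."""
    br, bc = _FOOTPRINTS[posture]
    br *= subject_scale
    bc *= subject_scale
    r0, c0 = center
    h, w = canvas.shape
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    body = ((rows - r0) / br) ** 2 + ((cols - c0) / bc) ** 2 <= 1.0
    head = ((rows - r0) ** 2 + (cols - c0) ** 2
            <= (_HEAD_RADIUS_PX * subject_scale) ** 2)
    head_depth = floor_depth_mm - head_height_mm
    body_depth = min(head_depth + 150.0, floor_depth_mm - 50.0)
    canvas[body] = body_depth
    canvas[head & body] = head_depth


def _sample_trajectory(traj: TrajectorySpec, fps: float):
    """Per-frame (head height, center, posture) samples."""
    samples = []
    t_accum = 0.0
    n_total = int(round(traj.total_duration_s * fps))
    frame_times = np.arange(n_total) / fps
    edges = np.cumsum([p.duration_s for p in traj.phases])
    starts = np.concatenate([[0.0], edges[:-1]])
    for t in frame_times:
        i = int(np.searchsorted(edges, t, side="right"))
        i = min(i, len(traj.phases) - 1)
        p = traj.phases[i]
        frac = (t - starts[i]) / p.duration_s
        frac = min(max(frac, 0.0), 1.0)
        head = p.head_start_mm + frac * (p.head_end_mm - p.head_start_mm)
        row = p.pos_start[0] + frac * (p.pos_end[0] - p.pos_start[0])
        col = p.pos_start[1] + frac * (p.pos_end[1] - p.pos_start[1])
        samples.append((head, (row, col), p.posture))
    return samples


def _finalize(canvas: np.ndarray, scene: SceneSpec,
              rng: np.random.Generator) -> np.ndarray:
    out = canvas.copy()
    if scene.noise_sigma_mm > 0:
        out = out + rng.normal(0.0, scene.noise_sigma_mm, size=out.shape)
    out = np.clip(out, 1.0, 65535.0)
    grid = np.rint(out).astype(np.uint16)
    if scene.border_px > 0 and scene.border_dropout_rate > 0:
        b = scene.border_px
        edge = np.zeros(grid.shape, dtype=bool)
        edge[:b, :] = edge[-b:, :] = True
        edge[:, :b] = edge[:, -b:] = True
        drop = rng.random(grid.shape) < scene.border_dropout_rate
        grid[edge & drop] = 0
    return grid


def render_sequence(traj: TrajectorySpec, subject: SubjectProfile,
                    scene: SceneSpec, params: DetectorParams,
                    background_duration_s: float = 1.0,
                    ) -> tuple[list[DepthFrame], list[DepthFrame]]:
    """Render a trajectory into depth frames plus a person-free background.

    Deterministic: a fixed (traj, subject, scene) — the seed lives in the
    scene — always yields bit-identical output.
    """
    rng = np.random.default_rng(scene.seed)
    base = _scene_base(scene, params)
    subject_scale = subject.height_cm / 176.0

    background: list[DepthFrame] = []
    n_bg = int(round(background_duration_s * params.fps))
    for i in range(n_bg):
        background.append(DepthFrame(grid=_finalize(base, scene, rng),
                                     timestamp_s=i / params.fps))

    frames: list[DepthFrame] = []
    for i, (head, center, posture) in enumerate(
            _sample_trajectory(traj, params.fps)):
        canvas = base.copy()
        br, bc = _FOOTPRINTS[posture]
        if (br * subject_scale > params.frame_height
                or bc * subject_scale > params.frame_width):
            raise ValueError("person footprint exceeds the frame")
        _person_layer(canvas, center, head, posture, subject_scale,
                      scene.floor_depth_mm)
        frames.append(DepthFrame(grid=_finalize(canvas, scene, rng),
                                 timestamp_s=i / params.fps))
    return frames, background


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _sequence_seed(master_seed: int, subject_id: str, code: ActionCode) -> int:
    digest = hashlib.sha256(
        f"{master_seed}:{subject_id}:{code}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def dataset_plan(subjects: Sequence[SubjectProfile],
                 codes: Optional[Sequence[ActionCode]] = None,
                 ) -> list[dict]:
    """Manifest rows (no rendering) for subjects x protocol actions."""
    if codes is None:
        codes = [code for code, _ in protocol_catalog()]
    rows = []
    for subject in subjects:
        for code in codes:
            rows.append({
                "sequence_dir": f"{subject.subject_id}/{code}",
                "subject_id": subject.subject_id,
                "action_code": str(code),
                "label": code.label.value,
            })
    return rows


def iter_sequences(subjects: Sequence[SubjectProfile],
                   codes: Optional[Sequence[ActionCode]] = None,
                   scene: SceneSpec = SceneSpec(),
                   params: DetectorParams = DetectorParams(),
                   master_seed: int = 0,
                   ) -> Iterator[tuple[dict, list[DepthFrame], list[DepthFrame]]]:
    """Render the dataset lazily, one sequence at a time.

    Yields ``(manifest_row, frames, background)``.  Rendering a sequence is
    a pure function of (master_seed, subject, code, scene), so the iterator
    can be re-run to stream the identical dataset without holding it in
    memory.
    """
    if codes is None:
        codes = [code for code, _ in protocol_catalog()]
    for subject in subjects:
        for code in codes:
            seed = _sequence_seed(master_seed, subject.subject_id, code)
            traj = trajectory_for_action(code, subject, rng_seed=seed)
            seq_scene = replace(scene, seed=seed)
            frames, background = render_sequence(traj, subject, seq_scene,
                                                 params)
            row = {
                "sequence_dir": f"{subject.subject_id}/{code}",
                "subject_id": subject.subject_id,
                "action_code": str(code),
                "label": code.label.value,
            }
            yield row, frames, background


def generate_dataset(subjects: Sequence[SubjectProfile],
                     codes: Optional[Sequence[ActionCode]],
                     scene: SceneSpec, out_root: str | Path,
                     params: DetectorParams = DetectorParams(),
                     master_seed: int = 0) -> Path:
    """Render and write |subjects| x |codes| sequences plus backgrounds.

    Returns the manifest path.  One background sequence is written per
    subject and shared by that subject's action sequences.
    """
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in subjects:
        bg_dir = out_root / f"background_{subject.subject_id}"
        bg_written = False
        for row, frames, background in iter_sequences(
                [subject], codes, scene, params, master_seed):
            if not bg_written:
                bg_meta = SequenceMeta(
                    subject_id=subject.subject_id, action_code="BACKGROUND",
                    fps=params.fps, sensor_height_mm=params.sensor_height_mm,
                    n_frames=len(background))
                write_sequence(background, bg_meta, bg_dir)
                bg_written = True
            seq_dir = out_root / row["sequence_dir"]
            meta = SequenceMeta(
                subject_id=subject.subject_id,
                action_code=row["action_code"],
                fps=params.fps, sensor_height_mm=params.sensor_height_mm,
                n_frames=len(frames),
                background_ref=str(bg_dir.relative_to(out_root)))
            write_sequence(frames, meta, seq_dir)
            rows.append(row)
    return write_labels(rows, out_root / "manifest.csv")


# ---------------------------------------------------------------------------
# Scripted edge cases (the acquisition campaign's failure narratives)
# ---------------------------------------------------------------------------

EDGE_CASE_NAMES = (
    "enter_while_falling",
    "border_fall",
    "exit_before_fall",
    "fast_recovery",
)


def edge_case_sequences(subject: SubjectProfile,
                        scene: SceneSpec = SceneSpec(),
                        params: DetectorParams = DetectorParams(),
                        master_seed: int = 0,
                        ) -> list[tuple[str, list[DepthFrame], list[DepthFrame], dict]]:
    """Render the four scripted failure-mode sequences.

    Each reproduces a known limitation of the height-tracking detector:

    - ``enter_while_falling``: the person is first seen already past the
      near-floor threshold; no upright reference can be enrolled and the
      sequence stays unclassified (``no_person``).
    - ``border_fall``: the person falls with the body mostly outside the
      coverage area; the blob shrinks below the minimum area, tracking is
      lost and the fall is missed (labelled ADL).
    - ``exit_before_fall``: the person is tracked but leaves the scene
      before falling; nothing can be detected (ADL).
    - ``fast_recovery``: a knee fall with a ground stay so short that the
      low-posture episode never reaches the evaluation window; the Warning
      is missed (ADL).

    Returns ``(name, frames, background, expectation)`` tuples where the
    expectation dict carries the detector outcome the script is designed to
    produce and the action's true label.
    """
    H = subject.height_mm
    out = []

    def render(name, phases, expectation, offset):
        seed = (master_seed * 7919 + offset) % (2 ** 31)
        traj = TrajectorySpec(phases=tuple(phases))
        frames, background = render_sequence(
            traj, subject, replace(scene, seed=seed), params)
        out.append((name, frames, background, expectation))

    # 1. Enters the scene already falling: first sighting is below the
    #    near-floor threshold (but above the person height gate), so the
    #    standing reference is refused.
    render(
        "enter_while_falling",
        [
            Phase("descend", 0.3, 450.0, LYING_HEAD_MM, "lying",
                  _CENTER, _CENTER),
            Phase("on_ground", 4.0, LYING_HEAD_MM, LYING_HEAD_MM, "lying",
                  _CENTER, _CENTER),
        ],
        {"detector_label": "ADL", "no_person": True, "true_label": "Fall"},
        offset=1,
    )

    # 2. Falls with the body almost entirely outside the coverage area.
    render(
        "border_fall",
        [
            Phase("enter", 1.0, H, H, "upright", _ENTER_FROM, (120.0, 40.0)),
            Phase("walk", 1.0, H, H, "upright", (120.0, 40.0), (120.0, 12.0)),
            Phase("descend", 0.7, H, LYING_HEAD_MM, "lying",
                  (120.0, 12.0), (120.0, -55.0)),
            Phase("on_ground", 4.0, LYING_HEAD_MM, LYING_HEAD_MM, "lying",
                  (120.0, -55.0), (120.0, -55.0)),
        ],
        {"detector_label": "ADL", "no_person": False, "true_label": "Fall"},
        offset=2,
    )

    # 3. Tracked, then leaves the field of view before falling.
    render(
        "exit_before_fall",
        [
            Phase("enter", 1.0, H, H, "upright", _ENTER_FROM, _WALK_START),
            Phase("walk", 2.0, H, H, "upright", _WALK_START, (120.0, 280.0)),
            Phase("exit", 1.0, H, H, "upright", (120.0, 280.0),
                  (120.0, 360.0)),
            Phase("stand", 3.0, H, H, "upright", (120.0, 430.0),
                  (120.0, 430.0)),
        ],
        {"detector_label": "ADL", "no_person": False, "true_label": "Fall"},
        offset=3,
    )

    # 4. Knee fall with a recovery faster than the 4 s evaluation window.
    render(
        "fast_recovery",
        [
            Phase("stand", 1.5, H, H, "upright", _CENTER, _CENTER),
            Phase("descend", 0.7, H, KNEELING_HEAD_MM, "kneeling",
                  _CENTER, _CENTER),
            Phase("on_ground", 1.2, KNEELING_HEAD_MM, KNEELING_HEAD_MM,
                  "kneeling", _CENTER, _CENTER),
            Phase("recover", 0.8, KNEELING_HEAD_MM, H, "upright",
                  _CENTER, _CENTER),
            Phase("stand", 1.0, H, H, "upright", _CENTER, _CENTER),
        ],
        {"detector_label": "ADL", "no_person": False, "true_label": "Warning"},
        offset=4,
    )

    return out
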