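"""Temporal fall / warning / ADL logic over a tracked person's head distance.

The detector watches the sensor-to-head distance of the tracked person.  Four
per-frame conditions drive it (``pers_dist`` is the standing reference stored
at enrolment, ``act_dist`` the current head distance):

1. near-floor:     ``act_dist > thresholdFall``            (strict)
2. tolerance:      ``th_var = 0.15 (SensorHeight - pers_dist)``
3. recovery:       ``|act_dist - pers_dist| < th_var  or  act_dist < pers_dist``
4. low posture:    ``act_dist - pers_dist > th_var``

Condition 1 sustained continuously for more than ``warning_time`` raises a
Warning, and for more than ``recovery_time`` a Fall.  Condition 3 after a
raised Fall downgrades it to Warning (the person got up).  Condition 4
sustained for more than ``shift_time + sit_time`` hands the last ``sit_time``
seconds of buffered person frames to the SVM frame classifier, which
arbitrates low postures the height rule cannot separate (knee falls vs.
sitting on furniture): a Fall answer raises a Fall like the height rule, an
ADL answer drops ``wait_time`` seconds from the buffer and suspends
re-evaluation until the low-posture episode ends.

A single frame failing a condition resets that condition's episode timer
("continuously").  Timer comparisons are strict, and the near-floor timer is
clamped at ``wind_time`` (the fall/warning evaluation horizon; inert at the
default configuration since ``recovery_time < wind_time``).  Every detected
fall appends a 1 to a flag array and every classifier ADL answer a 0; the
majority of flags arbitrates the final Fall-vs-ADL call when the classifier
pathway fired.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np

from .config import DetectorParams, SequenceLabel, threshold_fall, th_var
from .features import dvh
from .io import DepthFrame
from .segmentation import (
    AnthropometricGates,
    BackgroundModel,
    PersonBlob,
    TrackedPerson,
    build_background,
    enroll_pers_dist,
    extract_foreground,
    find_blobs,
    identify_person,
)

__all__ = [
    "Mode",
    "EventKind",
    "Event",
    "Observation",
    "DetectorState",
    "SequenceResult",
    "near_floor",
    "recovery_check",
    "low_posture_check",
    "associate_blob",
    "step",
    "sequence_verdict",
    "run_sequence",
    "track_frames",
]

#: Number of initial person frames whose head distances are medianed into
#: the standing reference pers_dist.
ENROLL_FRAMES = 5

#: Default L1 threshold for histogram-based person/object re-association.
DEFAULT_ASSOC_TAU = 0.5


class Mode(str, Enum):
    NO_PERSON = "NO_PERSON"
    TRACKING = "TRACKING"
    NEAR_FLOOR = "NEAR_FLOOR"
    WARNING = "WARNING"
    FALL = "FALL"
    ADL_WAIT = "ADL_WAIT"


class EventKind(str, Enum):
    WARNING_RAISED = "WarningRaised"
    FALL_RAISED = "FallRaised"
    FALL_DOWNGRADED = "FallDowngradedToWarning"
    ADL_RECOGNIZED = "ADLRecognized"


@dataclass(frozen=True)
class Event:
    timestamp_s: float
    kind: EventKind
    act_dist_mm: Optional[float] = None
    pers_dist_mm: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "t": self.timestamp_s,
            "event": self.kind.value,
            "act_dist": self.act_dist_mm,
            "pers_dist": self.pers_dist_mm,
        }


@dataclass
class Observation:
    """Per-frame input to the state machine."""

    timestamp_s: float
    frame: Optional[DepthFrame]
    person: Optional[PersonBlob]
    blobs: list[PersonBlob] = field(default_factory=list)


@dataclass
class DetectorState:
    """The state machine's memory across frames."""

    params: DetectorParams
    mode: Mode = Mode.NO_PERSON
    tracked: Optional[TrackedPerson] = None
    near_floor_since: Optional[float] = None
    low_posture_since: Optional[float] = None
    frame_buffer: deque = field(default_factory=deque)
    fall_flags: list[int] = field(default_factory=list)
    emitted_events: list[Event] = field(default_factory=list)
    enrollment_refused: bool = False

    # episode bookkeeping
    _enroll_acts: list[float] = field(default_factory=list)
    _warned_this_episode: bool = False
    _fell_this_episode: bool = False
    _classifier_fired_this_episode: bool = False
    _adl_suppressed: bool = False
    _warned_ever: bool = False
    _downgraded_ever: bool = False
    _prev_blob_count: int = 0
    _frame_index: int = 0
    _last_time: Optional[float] = None
    _person_ever_tracked: bool = False

    def __post_init__(self) -> None:
        self.frame_buffer = deque(self.frame_buffer,
                                  maxlen=self.params.buffer_capacity)

    @property
    def pers_dist_mm(self) -> Optional[float]:
        return self.tracked.pers_dist_mm if self.tracked else None

    def _emit(self, t: float, kind: EventKind, act: Optional[float]) -> None:
        self.emitted_events.append(
            Event(timestamp_s=t, kind=kind, act_dist_mm=act,
                  pers_dist_mm=self.pers_dist_mm))


@dataclass
class SequenceResult:
    """Outcome of running the detector over one sequence."""

    label: SequenceLabel
    events: list[Event]
    no_person: bool
    final_mode: Mode
    fall_flags: list[int]

    def to_dict(self) -> dict:
        return {
            "label": self.label.value,
            "no_person": self.no_person,
            "final_mode": self.final_mode.value,
            "fall_flags": self.fall_flags,
            "events": [e.to_dict() for e in self.events],
        }


# ---------------------------------------------------------------------------
# Per-frame predicates
# ---------------------------------------------------------------------------


def near_floor(act_dist_mm: float, params: DetectorParams) -> bool:
    """Near-floor condition: head strictly beyond the fall threshold."""
    return act_dist_mm > threshold_fall(params)


def recovery_check(act_dist_mm: float, pers_dist_mm: float,
                   params: DetectorParams) -> bool:
    """Recovery condition: head back within th_var of (or above) standing."""
    tol = th_var(params, pers_dist_mm)
    return abs(act_dist_mm - pers_dist_mm) < tol or act_dist_mm < pers_dist_mm


def low_posture_check(act_dist_mm: float, pers_dist_mm: float,
                      params: DetectorParams) -> bool:
    """Low-posture condition: head more than th_var below standing."""
    return act_dist_mm - pers_dist_mm > th_var(params, pers_dist_mm)


def associate_blob(prev_person_dvh: np.ndarray,
                   candidate_blobs: Sequence[PersonBlob],
                   tau: float = DEFAULT_ASSOC_TAU) -> Optional[PersonBlob]:
    """Re-associate the person after a person/object fusion event.

    Candidates' unit-sum depth histograms are compared to the person's last
    histogram; the nearest in L1 distance is returned provided the distance
    is below ``tau``.  On unit-sum vectors the L1 distance is at most 2, so
    tau is a scale-free threshold.
    """
    best: Optional[PersonBlob] = None
    best_dist = np.inf
    for blob in candidate_blobs:
        if blob.dvh is None:
            continue
        dist = float(np.abs(np.asarray(blob.dvh) - prev_person_dvh).sum())
        if dist < best_dist:
            best, best_dist = blob, dist
    if best is not None and best_dist < tau:
        return best
    return None


# ---------------------------------------------------------------------------
# The per-frame transition
# ---------------------------------------------------------------------------

FrameClassifier = Callable[[list[tuple[DepthFrame, np.ndarray]]], str]
"""Window classifier: maps buffered (frame, person mask) pairs to 'Fall'/'ADL'."""


def step(state: DetectorState, observation: Observation,
         params: DetectorParams,
         frame_classifier: Optional[FrameClassifier] = None,
         assoc_tau: float = DEFAULT_ASSOC_TAU) -> DetectorState:
    """Advance the detector by one frame."""
    t = observation.timestamp_s
    if state._last_time is not None and t < state._last_time:
        raise ValueError("observations must arrive in non-decreasing time")
    state._last_time = t

    person = observation.person

    # Person/object fusion: the person vanished while the number of blobs
    # grew — try to find them inside one of the (merged) objects by
    # histogram association before declaring the person lost.
    if (person is None and state.tracked is not None
            and state.tracked.last_blob is not None
            and state.tracked.last_blob.dvh is not None
            and len(observation.blobs) > state._prev_blob_count):
        candidates = list(observation.blobs)
        if observation.frame is not None:
            for blob in candidates:
                if blob.dvh is None:
                    blob.dvh = dvh(observation.frame, blob.mask, params)
        person = associate_blob(state.tracked.last_blob.dvh, candidates,
                                tau=assoc_tau)

    state._prev_blob_count = len(observation.blobs)
    frame_index = state._frame_index
    state._frame_index += 1

    if person is None:
        # Continuity broken: reset episode timers; a raised Fall stays raised.
        _reset_eq1_episode(state)
        _reset_eq4_episode(state)
        _update_mode(state)
        return state

    # --- enrolment of the standing reference -----------------------------
    if state.tracked is None and not state.enrollment_refused:
        if not state._enroll_acts and \
                person.act_dist_mm >= threshold_fall(params):
            # Entered the scene already falling: no upright reference can be
            # acquired, the person is never recognised.
            state.enrollment_refused = True
            _update_mode(state)
            return state
        state._enroll_acts.append(person.act_dist_mm)
        if len(state._enroll_acts) >= ENROLL_FRAMES:
            pers = enroll_pers_dist(state._enroll_acts, params)
            state.tracked = TrackedPerson(pers_dist_mm=pers,
                                          first_seen_frame=frame_index)
            state._person_ever_tracked = True
    elif state.enrollment_refused:
        _update_mode(state)
        return state

    # --- buffer the foreground-only frame --------------------------------
    if observation.frame is not None:
        if person.dvh is None:
            person.dvh = dvh(observation.frame, person.mask, params)
        state.frame_buffer.append((observation.frame, person.mask))
    if state.tracked is not None:
        state.tracked.last_blob = person

    if state.tracked is None:
        _update_mode(state)
        return state  # still collecting enrolment frames

    act = person.act_dist_mm
    pers = state.tracked.pers_dist_mm
    eq1 = near_floor(act, params)
    eq3 = recovery_check(act, pers, params)
    eq4 = low_posture_check(act, pers, params)

    # --- near-floor episode (warning / fall by dwell time) ----------------
    if eq1:
        if state.near_floor_since is None:
            state.near_floor_since = t
        dwell = min(t - state.near_floor_since, params.wind_time_s)
        if dwell > params.warning_time_s and not state._warned_this_episode:
            state._warned_this_episode = True
            state._warned_ever = True
            state._emit(t, EventKind.WARNING_RAISED, act)
        if dwell > params.recovery_time_s and not state._fell_this_episode:
            state._fell_this_episode = True
            state.fall_flags.append(1)
            state._emit(t, EventKind.FALL_RAISED, act)
            state.mode = Mode.FALL
    else:
        _reset_eq1_episode(state)

    # --- low-posture episode (SVM arbitration) ----------------------------
    if eq4:
        if state.low_posture_since is None:
            state.low_posture_since = t
        dwell = t - state.low_posture_since
        if (dwell > params.shift_time_s + params.sit_time_s
                and not state._classifier_fired_this_episode
                and not state._adl_suppressed
                and frame_classifier is not None):
            state._classifier_fired_this_episode = True
            n_window = int(round(params.sit_time_s * params.fps))
            window = list(state.frame_buffer)[-n_window:]
            answer = frame_classifier(window)
            if answer == "Fall":
                state.fall_flags.append(1)
                state._emit(t, EventKind.FALL_RAISED, act)
                state.mode = Mode.FALL
            else:
                state.fall_flags.append(0)
                state._emit(t, EventKind.ADL_RECOGNIZED, act)
                n_drop = int(round(params.wait_time_s * params.fps))
                for _ in range(min(n_drop, len(state.frame_buffer))):
                    state.frame_buffer.popleft()
                state._adl_suppressed = True
    else:
        _reset_eq4_episode(state)

    # --- recovery downgrade ----------------------------------------------
    if state.mode is Mode.FALL and eq3:
        state._downgraded_ever = True
        state._emit(t, EventKind.FALL_DOWNGRADED, act)
        state.mode = Mode.WARNING

    _update_mode(state)
    return state


def _reset_eq1_episode(state: DetectorState) -> None:
    state.near_floor_since = None
    state._warned_this_episode = False
    state._fell_this_episode = False


def _reset_eq4_episode(state: DetectorState) -> None:
    state.low_posture_since = None
    state._classifier_fired_this_episode = False
    state._adl_suppressed = False


def _update_mode(state: DetectorState) -> None:
    if state.mode is Mode.FALL:
        return  # sticky until downgraded
    if state._warned_ever or state._downgraded_ever:
        state.mode = Mode.WARNING
    elif state.near_floor_since is not None:
        state.mode = Mode.NEAR_FLOOR
    elif state._adl_suppressed:
        state.mode = Mode.ADL_WAIT
    elif state.tracked is not None:
        state.mode = Mode.TRACKING
    else:
        state.mode = Mode.NO_PERSON


# ---------------------------------------------------------------------------
# Sequence-level verdict and runner
# ---------------------------------------------------------------------------


def sequence_verdict(state: DetectorState) -> SequenceLabel:
    """Collapse a finished detector run into an ADL / Fall / Warning label.

    An uncancelled Fall whose flag array holds more ones than zeros is a
    Fall; a downgraded Fall, or any Warning raised without a terminal Fall,
    is a Warning; everything else is an ADL.
    """
    flags = state.fall_flags
    fall_candidate = bool(flags) and sum(flags) > len(flags) - sum(flags)
    if fall_candidate and state.mode is Mode.FALL:
        return SequenceLabel.FALL
    if fall_candidate or state._warned_ever or state._downgraded_ever:
        return SequenceLabel.WARNING
    return SequenceLabel.ADL


def track_frames(frames: Sequence[DepthFrame], bg: BackgroundModel,
                 params: DetectorParams,
                 gates: AnthropometricGates = AnthropometricGates(),
                 min_area_px: int = 150,
                 ) -> list[Observation]:
    """Segment and track the person across a sequence.

    Person selection per frame: the blob with the largest pixel overlap with
    the previously tracked person mask, if any overlaps; otherwise a fresh
    anthropometric acquisition via :func:`identify_person` (which only
    accepts upright-ish blobs, so a lying person is followed by overlap
    alone).  The returned observations feed :func:`step`.
    """
    observations: list[Observation] = []
    prev_mask: Optional[np.ndarray] = None
    for i, frame in enumerate(frames):
        t = i / params.fps
        fg = extract_foreground(frame, bg)
        blobs = find_blobs(fg, frame, min_area_px=min_area_px)
        person: Optional[PersonBlob] = None
        if prev_mask is not None and blobs:
            overlaps = [int(np.count_nonzero(b.mask & prev_mask))
                        for b in blobs]
            best = int(np.argmax(overlaps))
            if overlaps[best] > 0:
                person = blobs[best]
        if person is None:
            person = identify_person(blobs, params, gates=gates)
        prev_mask = person.mask if person is not None else None
        observations.append(Observation(timestamp_s=t, frame=frame,
                                        person=person, blobs=blobs))
    return observations


def run_sequence(frames: Sequence[DepthFrame],
                 background: Sequence[DepthFrame],
                 params: DetectorParams,
                 classifier: Optional[FrameClassifier] = None,
                 gates: AnthropometricGates = AnthropometricGates(),
                 ) -> SequenceResult:
    """Run the full detector over one sequence and return its verdict."""
    bg = build_background(background)
    state = DetectorState(params=params)
    for obs in track_frames(frames, bg, params, gates=gates):
        state = step(state, obs, params, frame_classifier=classifier)
    label = sequence_verdict(state)
    no_person = not state._person_ever_tracked
    if no_person:
        label = SequenceLabel.ADL
    return SequenceResult(label=label, events=list(state.emitted_events),
                          no_person=no_person, final_mode=state.mode,
                          fall_flags=list(state.fall_flags))
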