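import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depthfall.config import DetectorParams, SequenceLabel
from depthfall.state_machine import (
    DetectorState,
    EventKind,
    Mode,
    associate_blob,
    low_posture_check,
    near_floor,
    recovery_check,
    sequence_verdict,
    step,
)

from conftest import run_scalar_series, scalar_observation
from reference import reference_events

FPS = 30


def standing(n=60, level=1230):
    return [level] * n


class TestPredicates:
    @pytest.mark.parametrize("act,expected", [
        (2500, True), (2400, False), (1230, False), (2400.001, True),
    ])
    def test_near_floor_strict(self, params, act, expected):
        assert near_floor(act, params) is expected

    @pytest.mark.parametrize("act,pers,expected", [
        (2300, 2250, True),    # within th_var
        (1200, 1230, True),    # above the standing reference
        (2500, 1230, False),
    ])
    def test_recovery(self, params, act, pers, expected):
        assert recovery_check(act, pers, params) is expected

    @pytest.mark.parametrize("act,pers,expected", [
        (1600, 1230, True),
        (1400, 1230, False),
        (1230, 1230, False),
    ])
    def test_low_posture(self, params, act, pers, expected):
        assert low_posture_check(act, pers, params) is expected


class TestScriptedScenarios:
    def test_fall_stays_down(self, params):
        """2 s standing then 5 s on the floor: Warning at 1 s of floor
        dwell, Fall at 2 s, verdict Fall."""
        series = standing(60) + [2750] * 150
        state = run_scalar_series(series, params)
        kinds = [(e.kind, round(e.timestamp_s, 3))
                 for e in state.emitted_events]
        assert kinds == [(EventKind.WARNING_RAISED, round(91 / FPS, 3)),
                         (EventKind.FALL_RAISED, round(121 / FPS, 3))]
        assert state.mode is Mode.FALL
        assert sequence_verdict(state) is SequenceLabel.FALL

    def test_fall_with_recovery_downgraded(self, params):
        series = standing(60) + [2750] * 75 + standing(60)
        state = run_scalar_series(series, params)
        kinds = [e.kind for e in state.emitted_events]
        assert kinds == [EventKind.WARNING_RAISED, EventKind.FALL_RAISED,
                         EventKind.FALL_DOWNGRADED]
        assert sequence_verdict(state) is SequenceLabel.WARNING

    def test_warning_precedes_fall(self, params):
        series = standing(60) + [2750] * 150
        state = run_scalar_series(series, params)
        t = {e.kind: e.timestamp_s for e in state.emitted_events}
        assert t[EventKind.WARNING_RAISED] < t[EventKind.FALL_RAISED]

    def test_short_bend_is_silent(self, params):
        """1.5 s bend, never past the near-floor threshold: no events."""
        series = standing(60) + [2204] * 45 + standing(60)
        state = run_scalar_series(series, params)
        assert state.emitted_events == []
        assert sequence_verdict(state) is SequenceLabel.ADL

    def test_brief_floor_contact_is_warning_only(self, params):
        series = standing(60) + [2750] * 45 + standing(60)  # 1.5 s down
        state = run_scalar_series(series, params)
        assert [e.kind for e in state.emitted_events] == \
            [EventKind.WARNING_RAISED]
        assert sequence_verdict(state) is SequenceLabel.WARNING

    def test_classifier_fall_on_sustained_low_posture(self, params):
        """Kneeling-height dwell beyond shift+sit consults the classifier."""
        series = standing(60) + [2300] * 160
        state = run_scalar_series(series, params, classifier=lambda w: "Fall")
        assert [e.kind for e in state.emitted_events] == \
            [EventKind.FALL_RAISED]
        assert state.fall_flags == [1]
        assert sequence_verdict(state) is SequenceLabel.FALL

    def test_classifier_fall_then_recovery_is_warning(self, params):
        series = standing(60) + [2300] * 160 + standing(30)
        state = run_scalar_series(series, params, classifier=lambda w: "Fall")
        assert [e.kind for e in state.emitted_events] == \
            [EventKind.FALL_RAISED, EventKind.FALL_DOWNGRADED]
        assert sequence_verdict(state) is SequenceLabel.WARNING

    def test_classifier_adl_drops_buffer_and_suppresses(self, params):
        series = standing(60) + [2300] * 200
        state = run_scalar_series(series, params, classifier=lambda w: "ADL")
        assert [e.kind for e in state.emitted_events] == \
            [EventKind.ADL_RECOGNIZED]
        assert state.fall_flags == [0]
        assert sequence_verdict(state) is SequenceLabel.ADL
        # buffer was full (capacity) and lost wait_time x fps frames, then
        # kept filling afterwards back up to capacity
        assert len(state.frame_buffer) <= params.buffer_capacity

    def test_enrollment_refused_when_entering_fallen(self, params):
        series = [2600] * 120
        state = run_scalar_series(series, params)
        assert state.enrollment_refused
        assert state.tracked is None
        assert state.emitted_events == []

    def test_time_backwards_rejected(self, params):
        state = DetectorState(params=params)
        step(state, scalar_observation(1.0, 1230, params), params)
        with pytest.raises(ValueError):
            step(state, scalar_observation(0.5, 1230, params), params)


class TestBufferInvariants:
    def test_capacity_bound(self, params):
        state = run_scalar_series(standing(400), params)
        assert len(state.frame_buffer) == params.buffer_capacity == 121

    def test_adl_drop_removes_wait_time_frames(self, params):
        # stop right after the classifier fires so no refill happens
        n_fire = 60 + int(4 * FPS) + 2
        series = standing(60) + [2300] * (n_fire - 60)
        state = run_scalar_series(series, params, classifier=lambda w: "ADL")
        assert [e.kind for e in state.emitted_events] == \
            [EventKind.ADL_RECOGNIZED]
        expected = params.buffer_capacity - int(params.wait_time_s * FPS)
        assert len(state.frame_buffer) == expected


class TestAssociation:
    def _blob(self, level, params):
        obs = scalar_observation(0.0, level, params)
        blob = obs.person
        from depthfall.features import dvh
        blob.dvh = dvh(obs.frame, blob.mask, params)
        return blob

    def test_identical_histograms_match(self, params):
        a = self._blob(1230, params)
        b = self._blob(1230, params)
        assert associate_blob(a.dvh, [b]) is b

    def test_disjoint_histograms_rejected(self, params):
        a = self._blob(1230, params)
        b = self._blob(2500, params)
        assert associate_blob(a.dvh, [b], tau=0.5) is None

    def test_nearest_candidate_wins(self, params):
        ref = np.zeros(256)
        ref[100] = 1.0
        near = self._blob(1230, params)   # bin 104
        near.dvh = np.zeros(256)
        near.dvh[100] = 0.9
        near.dvh[101] = 0.1
        far = self._blob(1230, params)
        far.dvh = np.zeros(256)
        far.dvh[100] = 0.8
        far.dvh[99] = 0.2
        assert associate_blob(ref, [far, near]) is near

    def test_fusion_reassociation_keeps_tracking(self, params):
        """Person vanishes while blob count grows: histogram association
        finds them inside the merged component."""
        state = DetectorState(params=params)
        for i in range(10):
            state = step(state, scalar_observation(i / FPS, 1230, params),
                         params)
        assert state.tracked is not None
        buffered = len(state.frame_buffer)
        merged = self._blob(1230, params)
        distractor = self._blob(2000, params)
        from depthfall.state_machine import Observation
        obs = Observation(timestamp_s=10 / FPS,
                          frame=scalar_observation(10 / FPS, 1230,
                                                   params).frame,
                          person=None, blobs=[merged, distractor])
        state = step(state, obs, params)
        assert state.tracked.last_blob is merged
        assert len(state.frame_buffer) == buffered + 1


def _random_series(rng):
    """Piecewise-constant head-distance series with occasional dropouts."""
    series = [int(rng.integers(1000, 2300))] * int(rng.integers(5, 15))
    for _ in range(int(rng.integers(3, 12))):
        if rng.random() < 0.15:
            level = None
        else:
            level = int(rng.integers(900, 2950))
        series += [level] * int(rng.integers(3, 60))
    return series


class TestOracleEquivalence:
    @pytest.mark.parametrize("classifier_answer", [None, "Fall", "ADL"])
    def test_matches_brute_force_scanner(self, params, classifier_answer):
        rng = np.random.default_rng(2024)
        classifier = (None if classifier_answer is None
                      else (lambda w: classifier_answer))
        for _ in range(150):
            series = _random_series(rng)
            state = run_scalar_series(series, params, classifier=classifier)
            got = [(e.kind.value, e.timestamp_s)
                   for e in state.emitted_events]
            expected = reference_events(series, params, classifier_answer)
            assert got == expected, f"series={series}"


class TestMonotoneSeverity:
    def test_longer_floor_dwell_never_softens_a_fall(self, params):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            series = _random_series(rng)
            state = run_scalar_series(series, params)
            if sequence_verdict(state) is not SequenceLabel.FALL:
                continue
            # extend the final frame's dwell (the sequence ends un-recovered)
            longer = series + [series[-1]] * 60
            state2 = run_scalar_series(longer, params)
            assert sequence_verdict(state2) is SequenceLabel.FALL
            checked += 1
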