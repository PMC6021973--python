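"""Brute-force reference detector used as an independent oracle.

Instead of advancing per-frame timers, this implementation first scans the
whole scalar head-distance series for maximal runs of the near-floor and
low-posture conditions, derives the event firing times from the run
boundaries, and then merges them chronologically with the recovery
downgrade rule.  It shares no code with the incremental state machine.
"""

import numpy as np

from depthfall.config import threshold_fall, th_var
from depthfall.state_machine import ENROLL_FRAMES


def _runs(flags):
    """Maximal [start, end) index runs where flags is True."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def reference_events(series, params, classifier_answer=None):
    """Expected (kind, timestamp) event list for a scalar act_dist series.

    ``series`` holds head distances in mm or None for person-absent frames.
    ``classifier_answer`` is the constant answer ('Fall'/'ADL') of the frame
    classifier consulted on sustained low-posture episodes, or None when no
    classifier is attached.
    """
    fps = params.fps
    thF = threshold_fall(params)
    person_idx = [i for i, a in enumerate(series) if a is not None]
    if not person_idx or series[person_idx[0]] >= thF:
        return []
    if len(person_idx) < ENROLL_FRAMES:
        return []
    enroll_idx = person_idx[:ENROLL_FRAMES]
    vals = [series[i] for i in enroll_idx if series[i] < thF]
    pers = float(np.median(vals))
    tol = th_var(params, pers)
    start = enroll_idx[-1]

    n = len(series)
    evaluated = np.zeros(n, dtype=bool)
    eq1 = np.zeros(n, dtype=bool)
    eq3 = np.zeros(n, dtype=bool)
    eq4 = np.zeros(n, dtype=bool)
    for i in range(start, n):
        a = series[i]
        if a is None:
            continue
        evaluated[i] = True
        eq1[i] = a > thF
        eq3[i] = abs(a - pers) < tol or a < pers
        eq4[i] = a - pers > tol

    def fire_index(run, window):
        """First frame of the run whose clamped dwell exceeds the window.

        Dwell is the difference of the frame timestamps (i / fps), matching
        the timestamps the detector is actually fed.
        """
        s, e = run
        for i in range(s, e):
            if min(i / fps - s / fps, params.wind_time_s) > window:
                return i
        return None

    timed = []  # (frame index, order within frame, kind)
    for run in _runs(evaluated & eq1):
        w = fire_index(run, params.warning_time_s)
        if w is not None:
            timed.append((w, 0, "WarningRaised"))
        f = fire_index(run, params.recovery_time_s)
        if f is not None:
            timed.append((f, 1, "FallRaised"))
    if classifier_answer is not None:
        for run in _runs(evaluated & eq4):
            s, e = run
            c = None
            for i in range(s, e):
                if i / fps - s / fps > params.shift_time_s + params.sit_time_s:
                    c = i
                    break
            if c is not None:
                kind = ("FallRaised" if classifier_answer == "Fall"
                        else "ADLRecognized")
                timed.append((c, 2, kind))
    timed.sort()

    events = []
    in_fall = False
    k = 0
    for i in range(start, n):
        while k < len(timed) and timed[k][0] == i:
            events.append((timed[k][2], i / fps))
            if timed[k][2] == "FallRaised":
                in_fall = True
            k += 1
        if in_fall and evaluated[i] and eq3[i]:
            events.append(("FallDowngradedToWarning", i / fps))
            in_fall = False
    return events
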