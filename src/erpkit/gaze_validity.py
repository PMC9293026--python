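"""Gaze-based trial validity and session attentiveness.

Eye-tracker streams lose samples (blinks, head movement). Interior gaps
of at most 150 ms are filled by linear interpolation; a trial is valid
when valid gaze covers at least 50% of the 0–500 ms stimulus window, and
a participant counts as highly attentive when at least 60% of presented
trials were valid in *both* sessions.

Looking time is weighted by inter-sample interval (each sample covers
the span up to the next sample), which is robust to irregular
eye-tracker sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GazeStream


@dataclass(frozen=True)
class TrialGazeScore:
    trial_id: int
    looking_proportion: float
    valid: bool


def _invalid_runs(valid: np.ndarray):
    """(start, stop) index pairs (inclusive) of maximal invalid runs."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j + 1 < n and not valid[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def interpolate_gaps(gs: GazeStream, max_gap_ms: float = 150.0) -> GazeStream:
    """Fill short interior gaps by linear interpolation.

    A maximal run of invalid samples is filled only when it is bounded by
    valid samples on both sides and its duration — measured from the last
    valid sample before the run to the first valid sample after it — is
    at most ``max_gap_ms`` (inclusive). Edge gaps are never filled. The
    operation is idempotent and never invalidates a sample.
    """
    valid = gs.valid.copy()
    x = gs.x.copy()
    y = gs.y.copy()
    n = len(gs)
    for start, stop in _invalid_runs(gs.valid):
        if start == 0 or stop == n - 1:
            continue
        t0, t1 = gs.times[start - 1], gs.times[stop + 1]
        if (t1 - t0) * 1000.0 > max_gap_ms:
            continue
        tt = gs.times[start : stop + 1]
        frac = (tt - t0) / (t1 - t0) if t1 > t0 else np.zeros_like(tt)
        x[start : stop + 1] = gs.x[start - 1] + frac * (gs.x[stop + 1] - gs.x[start - 1])
        y[start : stop + 1] = gs.y[start - 1] + frac * (gs.y[stop + 1] - gs.y[start - 1])
        valid[start : stop + 1] = True
    return GazeStream(times=gs.times, x=x, y=y, valid=valid)


def trial_looking_proportion(
    gs: GazeStream,
    onset_time_s: float,
    window_ms: tuple = (0.0, 500.0),
    screen_bounds: tuple | None = None,
) -> float:
    """Fraction of the stimulus window covered by valid gaze.

    Each sample covers the interval from its own timestamp to the next
    sample's (the final sample extends by the preceding interval), and a
    sample contributes where that interval overlaps the window. With
    ``screen_bounds=(xmin, xmax, ymin, ymax)`` validity additionally
    requires on-screen coordinates. No samples in the window gives 0.
    """
    w0 = onset_time_s + window_ms[0] / 1000.0
    w1 = onset_time_s + window_ms[1] / 1000.0
    if len(gs) == 0 or w1 <= w0:
        return 0.0
    t = gs.times
    if len(t) > 1:
        next_t = np.empty_like(t)
        next_t[:-1] = t[1:]
        next_t[-1] = t[-1] + (t[-1] - t[-2])
    else:
        next_t = t + (w1 - w0)
    valid = gs.valid
    if screen_bounds is not None:
        xmin, xmax, ymin, ymax = screen_bounds
        on_screen = (gs.x >= xmin) & (gs.x <= xmax) & (gs.y >= ymin) & (gs.y <= ymax)
        valid = valid & on_screen
    overlap = np.clip(np.minimum(next_t, w1) - np.maximum(t, w0), 0.0, None)
    covered = float(overlap[valid].sum())
    return min(covered / (w1 - w0), 1.0)


def score_trials(
    gs: GazeStream,
    onset_times_s,
    trial_ids,
    window_ms: tuple = (0.0, 500.0),
    max_gap_ms: float = 150.0,
    screen_bounds: tuple | None = None,
) -> list:
    """Interpolate gaps once, then score every trial.

    A trial is valid when its looking proportion is at least 0.5
    (inclusive).
    """
    filled = interpolate_gaps(gs, max_gap_ms)
    scores = []
    for tid, onset in zip(trial_ids, onset_times_s):
        p = trial_looking_proportion(filled, onset, window_ms, screen_bounds)
        scores.append(TrialGazeScore(trial_id=tid, looking_proportion=p, valid=p >= 0.5))
    return scores


def session_attentiveness(scores, n_presented: int) -> float:
    """Percentage of valid trials relative to the number presented."""
    if n_presented < 1:
        raise ValueError("n_presented must be at least 1")
    return 100.0 * sum(s.valid for s in scores) / n_presented


def highly_attentive(
    pct_session1: float | None, pct_session2: float | None, threshold: float = 60.0
) -> bool:
    """True when both sessions reach the attentiveness threshold (inclusive).

    A missing session percentage makes the participant not highly
    attentive.
    """
    if pct_session1 is None or pct_session2 is None:
        return False
    if np.isnan(pct_session1) or np.isnan(pct_session2):
        return False
    return pct_session1 >= threshold and pct_session2 >= threshold
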