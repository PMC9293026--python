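"""Trial subsampling, averaging, peak identification and ERP features.

Feature definitions (windows inclusive, times relative to stimulus onset):

* P1 — most positive peak between 50 and 200 ms at Oz (checkerboards);
  peak latency and a 60-ms-window amplitude centred on the peak.
* N290 — most negative peak between 190 and 350 ms at mean(P7, P8)
  (faces); peak latency, 60-ms-window amplitude, and mean amplitude over
  190–350 ms.
* P400 — mean amplitude over 300–500 ms at mean(P7, P8); no peak measures
  (its morphology is too broad for stable peak picking).

When no matching-polarity peak lies in a component's window the search
widens by 20 ms on each side, once; if there is still none the component
is invalid and its peak-based features are missing. A selected peak whose
point amplitude does not exceed the largest same-polarity peak in the
baseline (-100..0 ms) is rejected as baseline noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import TrialSet, baseline_correct

#: channels averaged per condition set
CONDITION_SET_CHANNELS = {
    "checkerboard": ("Oz",),
    "faces_all": ("P7", "P8"),
    "faces_upright": ("P7", "P8"),
    "faces_inverted": ("P7", "P8"),
}

#: trial-count grids per condition set; None means "all available"
TRIAL_GRIDS = {
    "checkerboard": (10, 20, 30, 40, 50, None),
    "faces_all": (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, None),
    "faces_upright": (10, 20, 30, 40, 50, 60, None),
    "faces_inverted": (10, 20, 30, 40, 50, 60, None),
}


@dataclass(frozen=True)
class ComponentWindow:
    """Search window and measure set for one ERP component."""

    name: str
    polarity: int
    window_ms: tuple
    widen_ms: float = 20.0
    measures: tuple = ("peak_latency", "peak_amplitude")

    def __post_init__(self):
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window must satisfy lo < hi")
        if self.widen_ms < 0:
            raise ValueError("widen_ms must be non-negative")


DEFAULT_WINDOWS = (
    ComponentWindow("P1", +1, (50.0, 200.0), 20.0, ("peak_latency", "peak_amplitude")),
    ComponentWindow(
        "N290", -1, (190.0, 350.0), 20.0, ("peak_latency", "peak_amplitude", "mean_amplitude")
    ),
    ComponentWindow("P400", +1, (300.0, 500.0), 20.0, ("mean_amplitude",)),
)

#: component sets applicable per condition set
CONDITION_SET_COMPONENTS = {
    "checkerboard": ("P1",),
    "faces_all": ("N290", "P400"),
    "faces_upright": ("N290", "P400"),
    "faces_inverted": ("N290", "P400"),
}


@dataclass(frozen=True)
class ERPWaveform:
    """A baseline-corrected average with its time axis and provenance."""

    data: np.ndarray
    time_ms: np.ndarray
    subject: object = None
    session: object = None
    condition_set: str | None = None
    n_trials: int = 0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "time_ms", np.asarray(self.time_ms, dtype=float))
        if self.data.shape != self.time_ms.shape:
            raise ValueError("data and time axis must have the same shape")


@dataclass(frozen=True)
class PeakResult:
    """One selected component peak (or the reason there is none)."""

    polarity: int
    latency_ms: float = np.nan
    point_amp: float = np.nan
    win_amp: float = np.nan
    valid: bool = False
    widened: bool = False
    reject_reason: str = "none"  # none | no_peak | baseline_noise


# ---------------------------------------------------------------------------
# subsampling and averaging


def subsample_trials(
    ts: TrialSet, n: int | None, balance: bool = False, seed: int = 0
) -> np.ndarray | None:
    """Choose ``n`` clean trials without replacement (deterministic in seed).

    With ``balance`` the draw takes exactly n/2 upright and n/2 inverted
    face trials. ``n=None`` means all clean trials. Returns ``None`` when
    not enough clean trials are available (the subject/session is simply
    unavailable at this trial count, not an error).
    """
    clean = ts.clean_indices()
    if n is None:
        return clean.copy()
    rng = np.random.default_rng(seed)
    if balance:
        if n % 2:
            raise ValueError("balanced subsampling needs an even n")
        conds = np.asarray(ts.conditions)
        up = clean[conds[clean] == "face_upright"]
        inv = clean[conds[clean] == "face_inverted"]
        half = n // 2
        if len(up) < half or len(inv) < half:
            return None
        chosen = np.concatenate(
            [rng.choice(up, half, replace=False), rng.choice(inv, half, replace=False)]
        )
        return np.sort(chosen)
    if len(clean) < n:
        return None
    return np.sort(rng.choice(clean, n, replace=False))


def average_trials(
    ts: TrialSet,
    indices: Sequence[int],
    channels: Sequence[str],
    baseline_ms: tuple = (-100.0, 0.0),
    **meta,
) -> ERPWaveform:
    """Average selected trials, then channels, then re-apply the baseline."""
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        raise ValueError("cannot average an empty trial selection")
    ch_idx = [ts.channel_index(c) for c in channels]
    avg = ts.trials[indices][:, ch_idx, :].mean(axis=0).mean(axis=0)
    avg = baseline_correct(avg, ts.time_ms, baseline_ms)
    meta.setdefault("n_trials", len(indices))
    return ERPWaveform(data=avg, time_ms=ts.time_ms, **meta)


# ---------------------------------------------------------------------------
# peak identification


def detect_peaks(y: np.ndarray) -> list:
    """All positive and negative peaks, in sample order.

    A sample is a positive peak when it is strictly higher than both
    neighbours. Where consecutive samples share the same amplitude the run
    counts as a single candidate, peaking at its last sample provided the
    run is preceded and followed by lower values (for a two-sample
    plateau: if the sample after the plateau deflects downward the second
    plateau sample is the peak, otherwise the run is a rising plateau and
    is skipped). Mirror logic gives negative peaks; endpoints are never
    peaks. Returns ``[(polarity, index), ...]``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples to detect peaks")
    peaks = []
    run_start = 0
    for i in range(1, n + 1):
        if i < n and y[i] == y[run_start]:
            continue
        run_end = i - 1
        if run_start > 0 and run_end < n - 1:
            prev, nxt, v = y[run_start - 1], y[run_end + 1], y[run_start]
            if prev < v and nxt < v:
                peaks.append((+1, run_end))
            elif prev > v and nxt > v:
                peaks.append((-1, run_end))
        run_start = i
    return peaks


def _peaks_in_window(peaks, polarity, time_ms, lo, hi):
    return [
        (p, i) for (p, i) in peaks if p == polarity and lo <= time_ms[i] <= hi
    ]


def select_component_peak(
    peaks: Sequence[tuple], comp: ComponentWindow, wave: ERPWaveform
) -> PeakResult:
    """Pick the component's peak from the detected-peak list.

    A single matching-polarity peak in the window is taken as-is; with
    several, the one with the largest amplitude in the polarity direction
    wins (ties: earliest). With none, the window widens by ``widen_ms`` on
    each side and the selection re-runs; if that also fails the component
    is invalid (``no_peak``).
    """
    lo, hi = comp.window_ms
    for widened, (wlo, whi) in enumerate(
        [(lo, hi), (lo - comp.widen_ms, hi + comp.widen_ms)]
    ):
        cands = _peaks_in_window(peaks, comp.polarity, wave.time_ms, wlo, whi)
        if cands:
            best = max(cands, key=lambda pi: (comp.polarity * wave.data[pi[1]], -pi[1]))
            idx = best[1]
            return PeakResult(
                polarity=comp.polarity,
                latency_ms=float(wave.time_ms[idx]),
                point_amp=float(wave.data[idx]),
                win_amp=peak_window_amplitude(wave, float(wave.time_ms[idx])),
                valid=True,
                widened=bool(widened),
            )
    return PeakResult(polarity=comp.polarity, valid=False, reject_reason="no_peak")


def baseline_noise_check(
    wave: ERPWaveform,
    peaks: Sequence[tuple],
    peak: PeakResult,
    baseline_ms: tuple = (-100.0, 0.0),
) -> bool:
    """True when the component peak clears the baseline-noise criterion.

    The peak's *point* amplitude must strictly exceed, in the polarity
    direction, the point amplitude of the largest same-polarity detected
    peak inside the baseline window; a waveform with no same-polarity
    baseline peak always passes.
    """
    if not peak.valid:
        raise ValueError("baseline_noise_check requires a valid peak")
    base = _peaks_in_window(peaks, peak.polarity, wave.time_ms, *baseline_ms)
    if not base:
        return True
    largest = max(peak.polarity * wave.data[i] for _, i in base)
    return peak.polarity * peak.point_amp > largest


# ---------------------------------------------------------------------------
# amplitude measures


def peak_window_amplitude(wave: ERPWaveform, latency_ms: float, halfwidth_ms: float = 30.0) -> float:
    """Mean amplitude over a 60-ms window centred on the peak (edge-clipped)."""
    mask = (wave.time_ms >= latency_ms - halfwidth_ms) & (
        wave.time_ms <= latency_ms + halfwidth_ms
    )
    if not mask.any():
        raise ValueError("amplitude window does not intersect the epoch")
    return float(wave.data[mask].mean())


def mean_amplitude(wave: ERPWaveform, window_ms: tuple) -> float:
    """Arithmetic mean over the inclusive sample range of ``window_ms``."""
    mask = (wave.time_ms >= window_ms[0]) & (wave.time_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} outside the epoch")
    return float(wave.data[mask].mean())


# ---------------------------------------------------------------------------
# feature extraction


def extract_features(
    wave: ERPWaveform,
    components: Sequence[ComponentWindow] = DEFAULT_WINDOWS,
    condition_set: str | None = None,
    baseline_ms: tuple = (-100.0, 0.0),
    return_peaks: bool = False,
):
    """All applicable ERP features for one averaged waveform.

    Peak-based features of an invalid (or baseline-noise-rejected) peak
    are missing (NaN); mean amplitudes never depend on a peak and are
    always computed. Returns a flat dict (and the PeakResults when
    ``return_peaks``).
    """
    condition_set = condition_set or wave.condition_set
    applicable = CONDITION_SET_COMPONENTS.get(condition_set)
    if applicable is None:
        raise ValueError(f"unknown condition set {condition_set!r}")
    peaks = detect_peaks(wave.data)
    row: dict = {}
    results: dict = {}
    for comp in components:
        if comp.name not in applicable:
            continue
        wants_peak = "peak_latency" in comp.measures or "peak_amplitude" in comp.measures
        if wants_peak:
            pr = select_component_peak(peaks, comp, wave)
            if pr.valid and not baseline_noise_check(wave, peaks, pr, baseline_ms):
                pr = PeakResult(polarity=comp.polarity, valid=False, reject_reason="baseline_noise")
            results[comp.name] = pr
            if "peak_latency" in comp.measures:
                row[f"{comp.name}_latency"] = pr.latency_ms if pr.valid else np.nan
            if "peak_amplitude" in comp.measures:
                key = f"{comp.name}_peak_amp" if "mean_amplitude" in comp.measures else f"{comp.name}_amp"
                row[key] = pr.win_amp if pr.valid else np.nan
        if "mean_amplitude" in comp.measures:
            row[f"{comp.name}_mean_amp"] = mean_amplitude(wave, comp.window_ms)
    return (row, results) if return_peaks else row


def grand_average(
    waves: Sequence[ERPWaveform], min_trials: int = 10, min_abs_amp: float = 1.0
) -> ERPWaveform:
    """Mean over eligible individual averages.

    A wave is eligible when its source had at least ``min_trials``
    artifact-free trials and its maximum absolute amplitude exceeds
    ``min_abs_amp`` (limited-signal screening).
    """
    eligible = [
        w
        for w in waves
        if w.n_trials >= min_trials and np.abs(w.data).max() > min_abs_amp
    ]
    if not eligible:
        raise ValueError("no waveform eligible for the grand average")
    data = np.mean([w.data for w in eligible], axis=0)
    return ERPWaveform(
        data=data,
        time_ms=eligible[0].time_ms,
        condition_set=eligible[0].condition_set,
        n_trials=min(w.n_trials for w in eligible),
    )
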