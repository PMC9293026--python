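"""Epoching, filtering, artifact flagging and trial-wise re-referencing.

The pipeline order is fixed and deliberate:

    segment -> bandpass -> dft line filter -> baseline correction ->
    artifact flagging -> bad-channel exclusion -> condition rules ->
    trial-wise re-referencing

Filters run on the padded raw context of each trial (3 s on both sides,
real data when available, reflection otherwise) and results are cropped
back to the -100..600 ms epoch. Flags are computed once on the
pre-re-reference signal; channel badness (the 80% rule) is assessed after
filtering and before trial exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal

from .io_formats import EventList, Recording

#: analysis channels per condition family
FAMILY_CHANNELS = {"checkerboard": ("Oz",), "faces": ("P7", "P8")}
FAMILY_CONDITIONS = {
    "checkerboard": ("checkerboard",),
    "faces": ("face_upright", "face_inverted"),
}


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters (units: Hz, s, ms, µV).

    ``flat_eps`` and ``amp_thresh`` implement the artifact rules: a
    channel is flat in a trial when its maximum absolute amplitude does
    not exceed ``flat_eps`` (0.0001 µV), and an amplitude artifact when
    any sample strictly exceeds ±``amp_thresh`` (150 µV). A channel is
    excluded when flagged in at least ``bad_channel_prop`` of trials.
    """

    bp_lo: float = 0.1
    bp_hi: float = 40.0
    filter_order: int = 4
    pad_s: float = 3.0
    line_freqs: tuple = (50.0, 100.0, 150.0)
    baseline_ms: tuple = (-100.0, 0.0)
    window_ms: tuple = (-100.0, 600.0)
    flat_eps: float = 1e-4
    amp_thresh: float = 150.0
    bad_channel_prop: float = 0.8
    ref_primary: str = "Cz"
    ref_fallback: tuple = ("C3", "C4")

    def __post_init__(self):
        if not 0.0 < self.bp_lo < self.bp_hi:
            raise ValueError("need 0 < bp_lo < bp_hi")
        if not 0.0 < self.bad_channel_prop <= 1.0:
            raise ValueError("bad_channel_prop must be in (0, 1]")

    def validate_for_fs(self, fs: float) -> None:
        if self.bp_hi >= fs / 2:
            raise ValueError(f"bp_hi={self.bp_hi} must be below Nyquist ({fs / 2})")


@dataclass
class TrialSet:
    """Per-trial epochs with artifact flags and exclusion bookkeeping.

    ``trials`` holds the (n_trials, n_channels, n_times) epoch matrices in
    µV cropped to the analysis window; ``padded`` the raw context used for
    filtering. ``flags`` is True where a channel shows an artifact in a
    trial (``flag_flat``/``flag_amp`` record the reason separately).
    """

    trials: np.ndarray
    time_ms: np.ndarray
    fs: float
    channels: tuple
    conditions: tuple
    trial_ids: tuple
    padded: np.ndarray | None = None
    pad_samples: int = 0
    reflect_padded: np.ndarray | None = None
    flags: np.ndarray | None = None
    flag_flat: np.ndarray | None = None
    flag_amp: np.ndarray | None = None
    bad_channels: tuple = ()
    excluded: np.ndarray = None
    excl_reason: list = field(default_factory=list)
    reference_used: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.trials)
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        if not self.excl_reason:
            self.excl_reason = [""] * n
        if not self.reference_used:
            self.reference_used = ["none"] * n

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_clean(self) -> int:
        return int((~self.excluded).sum())

    def clean_indices(self) -> np.ndarray:
        return np.nonzero(~self.excluded)[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in trial set") from None

    def exclusion_log(self):
        """(trial_id, reason) rows for every excluded trial."""
        return [
            {"trial_id": self.trial_ids[i], "reason": self.excl_reason[i]}
            for i in np.nonzero(self.excluded)[0]
        ]


def _window_samples(window_ms, fs):
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    return lo, hi


def segment(
    rec: Recording,
    events: EventList,
    window_ms: tuple = (-100.0, 600.0),
    pad_s: float = 3.0,
) -> TrialSet:
    """Cut padded epochs around each event onset.

    The epoch spans ``window_ms`` inclusive at the recording's sampling
    rate (t = 0 at the onset sample). ``pad_s`` of real context is kept on
    both sides for the filters; where the recording is too short the
    context is reflect-padded and the trial logged in
    ``reflect_padded``. Trials whose analysis window itself falls outside
    the recording are excluded with reason ``"edge"``.
    """
    fs = rec.fs
    lo, hi = _window_samples(window_ms, fs)
    pad_n = int(round(pad_s * fs))
    n_times = hi - lo + 1
    n_pad_total = n_times + 2 * pad_n
    n_ch = len(rec.channels)
    n_trials = len(events)

    trials = np.zeros((n_trials, n_ch, n_times))
    padded = np.zeros((n_trials, n_ch, n_pad_total))
    excluded = np.zeros(n_trials, dtype=bool)
    reasons = [""] * n_trials
    reflect = np.zeros(n_trials, dtype=bool)

    for k, onset in enumerate(events.onsets):
        w_start, w_stop = onset + lo, onset + hi  # inclusive
        if w_start < 0 or w_stop >= rec.n_samples:
            excluded[k] = True
            reasons[k] = "edge"
            continue
        p_start, p_stop = w_start - pad_n, w_stop + pad_n
        if p_start < 0 or p_stop >= rec.n_samples:
            reflect[k] = True
            left = max(0, -p_start)
            right = max(0, p_stop - (rec.n_samples - 1))
            chunk = rec.data[:, max(0, p_start) : min(rec.n_samples, p_stop + 1)]
            chunk = np.pad(chunk, ((0, 0), (left, right)), mode="reflect")
        else:
            chunk = rec.data[:, p_start : p_stop + 1]
        padded[k] = chunk
        trials[k] = chunk[:, pad_n : pad_n + n_times]

    time_ms = (np.arange(lo, hi + 1) / fs) * 1000.0
    return TrialSet(
        trials=trials,
        time_ms=time_ms,
        fs=fs,
        channels=rec.channels,
        conditions=events.conditions,
        trial_ids=events.trial_ids,
        padded=padded,
        pad_samples=pad_n,
        reflect_padded=reflect,
        excluded=excluded,
        excl_reason=reasons,
    )


# ---------------------------------------------------------------------------
# filters


def design_bandpass(fs: float, lo: float, hi: float, order: int = 4):
    """Butterworth band-pass in second-order sections (applied two-pass)."""
    return scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    padded: np.ndarray, fs: float, lo: float = 0.1, hi: float = 40.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Two-pass (forward-backward) filtering squares the magnitude response
    and cancels the phase, preserving peak latencies.
    """
    if not np.all(np.isfinite(padded)):
        raise ValueError("non-finite samples in input to bandpass_filter")
    sos = design_bandpass(fs, lo, hi, order)
    return scipy.signal.sosfiltfilt(sos, padded, axis=-1)


def bandpass_gain(f_hz: float, fs: float, lo: float = 0.1, hi: float = 40.0, order: int = 4) -> float:
    """Two-pass magnitude gain of the designed band-pass at ``f_hz``."""
    sos = design_bandpass(fs, lo, hi, order)
    _, h = scipy.signal.sosfreqz(sos, worN=[f_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def dft_line_filter(
    padded: np.ndarray, fs: float, freqs: Sequence[float] = (50.0, 100.0, 150.0)
) -> np.ndarray:
    """Remove line-frequency sinusoids by least-squares fit-and-subtract.

    For each frequency a sine/cosine pair over the full (padded) segment
    is fit by least squares and subtracted, cancelling a stationary
    sinusoid exactly when the segment spans integer cycles.
    """
    padded = np.asarray(padded, dtype=float)
    n = padded.shape[-1]
    t = np.arange(n) / fs
    cols = []
    for f in freqs:
        cols.append(np.sin(2 * np.pi * f * t))
        cols.append(np.cos(2 * np.pi * f * t))
    X = np.stack(cols, axis=1)  # (n, 2F)
    flat = padded.reshape(-1, n).T  # (n, m)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    cleaned = flat - X @ coef
    return cleaned.T.reshape(padded.shape)


def crop_padded(padded: np.ndarray, pad_samples: int, n_times: int) -> np.ndarray:
    """Crop the filtered padded segment back to the analysis window."""
    return padded[..., pad_samples : pad_samples + n_times]


def baseline_correct(
    waves: np.ndarray, time_ms: np.ndarray, window_ms: tuple = (-100.0, 0.0)
) -> np.ndarray:
    """Subtract the mean over the baseline window (inclusive) per channel."""
    mask = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} outside time axis")
    return waves - waves[..., mask].mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# artifact rules


def flag_artifacts(trials: np.ndarray, flat_eps: float = 1e-4, amp_thresh: float = 150.0):
    """Per trial x channel artifact flags on baseline-corrected epochs.

    Flat: max |amplitude| over the epoch does not exceed ``flat_eps``
    (<=, i.e. "did not exceed"). Amplitude: any sample strictly exceeds
    ±``amp_thresh`` (a sample exactly at the threshold is retained).
    Returns ``(flags, flat, amp)`` boolean (n_trials, n_channels) arrays.
    """
    absmax = np.abs(trials).max(axis=-1)
    flat = absmax <= flat_eps
    amp = absmax > amp_thresh
    return flat | amp, flat, amp


def exclude_bad_channels(flags: np.ndarray, prop: float = 0.8) -> np.ndarray:
    """Boolean per-channel mask: flagged in >= ``prop`` of trials ("or above")."""
    if len(flags) == 0:
        raise ValueError("need at least one trial")
    return flags.mean(axis=0) >= prop


def rereference(ts: TrialSet, cfg: PreprocConfig) -> TrialSet:
    """Trial-wise re-referencing to Cz, falling back to mean(C3, C4).

    Per retained trial: Cz unflagged -> subtract Cz; else both fallback
    channels unflagged -> subtract their mean; else the trial is excluded
    (reason ``"no_reference"``). Operates in place on ``ts.trials``.
    """
    for label in (cfg.ref_primary, *cfg.ref_fallback):
        if label not in ts.channels:
            raise ValueError(f"reference channel {label!r} absent from recording")
    ci_primary = ts.channel_index(cfg.ref_primary)
    ci_fb = [ts.channel_index(c) for c in cfg.ref_fallback]
    fb_label = f"mean({','.join(cfg.ref_fallback)})"
    for k in range(len(ts)):
        if ts.excluded[k]:
            continue
        if not ts.flags[k, ci_primary]:
            ref = ts.trials[k, ci_primary]
            ts.reference_used[k] = cfg.ref_primary
        elif not any(ts.flags[k, ci] for ci in ci_fb):
            ref = ts.trials[k][ci_fb].mean(axis=0)
            ts.reference_used[k] = fb_label
        else:
            ts.excluded[k] = True
            ts.excl_reason[k] = "no_reference"
            continue
        ts.trials[k] = ts.trials[k] - ref[None, :]
    return ts


def apply_condition_rules(ts: TrialSet, cfg: PreprocConfig, family: str) -> TrialSet:
    """Condition-family trial exclusion followed by re-referencing.

    Checkerboard trials are excluded when Oz is flagged (or Oz is a bad
    channel); face trials when P7 and/or P8 is flagged or bad.
    """
    try:
        analysis = FAMILY_CHANNELS[family]
    except KeyError:
        raise ValueError(f"unknown condition family {family!r}") from None
    bad_idx = [ts.channel_index(c) for c in ts.bad_channels]
    for k in range(len(ts)):
        if ts.excluded[k]:
            continue
        for ch in analysis:
            ci = ts.channel_index(ch)
            if ts.flags[k, ci] or ci in bad_idx:
                ts.excluded[k] = True
                ts.excl_reason[k] = f"artifact_{ch}"
                break
    return rereference(ts, cfg)


# ---------------------------------------------------------------------------
# orchestration


def preprocess_session(
    rec: Recording,
    events: EventList,
    family: str,
    cfg: PreprocConfig = PreprocConfig(),
) -> TrialSet:
    """Run the full fixed-order preprocessing for one condition family."""
    cfg.validate_for_fs(rec.fs)
    conds = FAMILY_CONDITIONS[family]
    keep = [i for i, c in enumerate(events.conditions) if c in conds]
    ev = EventList(
        onsets=events.onsets[keep],
        conditions=tuple(events.conditions[i] for i in keep),
        trial_ids=tuple(events.trial_ids[i] for i in keep),
    )
    ts = segment(rec, ev, cfg.window_ms, cfg.pad_s)
    if len(ts) == 0:
        ts.flags = np.zeros((0, len(rec.channels)), dtype=bool)
        return ts
    n_times = len(ts.time_ms)
    filtered = bandpass_filter(ts.padded, ts.fs, cfg.bp_lo, cfg.bp_hi, cfg.filter_order)
    filtered = dft_line_filter(filtered, ts.fs, cfg.line_freqs)
    ts.trials = baseline_correct(
        crop_padded(filtered, ts.pad_samples, n_times), ts.time_ms, cfg.baseline_ms
    )
    ts.padded = None  # large; no longer needed
    ts.flags, ts.flag_flat, ts.flag_amp = flag_artifacts(
        ts.trials, cfg.flat_eps, cfg.amp_thresh
    )
    bad_mask = exclude_bad_channels(ts.flags, cfg.bad_channel_prop)
    ts.bad_channels = tuple(c for c, b in zip(ts.channels, bad_mask) if b)
    return apply_condition_rules(ts, cfg, family)
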