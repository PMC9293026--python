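"""Synthetic toddler ERP sessions with known ground truth.

The simulator emulates the study conditions the pipeline is built for:
8-channel, 500-Hz EEG sessions containing a checkerboard condition (P1 at
Oz) and upright/inverted face conditions (N290 and P400 at P7/P8), with
1/f background noise, a small common-mode background, planted flat-channel
and high-amplitude artifacts, gaze streams with gap structure, and
per-subject latent component parameters drawn from a between/within
variance model whose implied intraclass correlation is analytic:

    true ICC = sd_between^2 / (sd_between^2 + sd_within^2)

Component morphology is a Gaussian bump — the peak-picking downstream
assumes a smooth unimodal deflection, and a Gaussian gives closed-form
truth for latency and windowed amplitude.

Every source of randomness is derived from one seed through
``numpy.random.SeedSequence``; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DEFAULT_CHANNELS, EventList, GazeStream, Recording

FS = 500.0  # Hz

#: identical low-amplitude background added to every channel; it keeps
#: noiseless channels from triggering the flat-signal artifact rule and
#: cancels exactly under re-referencing (common mode).
BACKGROUND_AMP_UV = 0.5
BACKGROUND_FREQ_HZ = 6.0


@dataclass(frozen=True)
class ComponentSpec:
    """Latent model for one ERP component.

    Latencies in ms, amplitudes in µV (magnitude; ``polarity`` carries the
    sign). ``width`` is the Gaussian SD of the bump in ms. Between-subject
    SDs generate stable individual differences; within-subject SDs
    generate session-to-session change, so the implied test-retest ICC of
    each parameter is sd_between^2/(sd_between^2+sd_within^2).
    """

    name: str
    channels: tuple
    polarity: int
    mu_latency: float
    sd_latency_between: float
    sd_latency_within: float
    mu_amp: float
    sd_amp_between: float
    sd_amp_within: float
    width: float

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.width <= 0:
            raise ValueError("width must be positive")
        for sd in (
            self.sd_latency_between,
            self.sd_latency_within,
            self.sd_amp_between,
            self.sd_amp_within,
        ):
            if sd < 0:
                raise ValueError("SDs must be non-negative")

    def true_icc_latency(self) -> float:
        return _variance_ratio(self.sd_latency_between, self.sd_latency_within)

    def true_icc_amp(self) -> float:
        return _variance_ratio(self.sd_amp_between, self.sd_amp_within)


def _variance_ratio(sd_b: float, sd_w: float) -> float:
    denom = sd_b**2 + sd_w**2
    return float("nan") if denom == 0 else sd_b**2 / denom


#: Defaults place each bump comfortably inside its search window (P1:
#: 50-200 ms; N290: 190-350 ms; P400: 300-500 ms) and keep the overlap
#: between the opposite-polarity N290 and P400 small enough that neither
#: shifts the other's extremum by more than one sample at 500 Hz.
DEFAULT_COMPONENTS = (
    ComponentSpec("P1", ("Oz",), +1, 120.0, 8.0, 4.0, 8.0, 1.5, 1.0, 20.0),
    ComponentSpec("N290", ("P7", "P8"), -1, 260.0, 10.0, 5.0, 6.0, 1.5, 1.0, 25.0),
    ComponentSpec("P400", ("P7", "P8"), +1, 420.0, 12.0, 6.0, 5.0, 1.2, 0.8, 55.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level simulation parameters.

    Trial budgets default to the task structure the pipeline targets:
    72 checkerboard trials and 72+72 upright/inverted face trials per
    session. ``noise_sd`` is the RMS of the single-trial background in µV.
    """

    n_subjects: int = 38
    n_sessions: int = 2
    n_checkerboard: int = 72
    n_face_upright: int = 72
    n_face_inverted: int = 72
    noise_sd: float = 20.0
    pink_exponent: float = 1.0
    artifact_rate_amp: float = 0.05
    artifact_rate_flat: float = 0.02
    gaze_gap_rate: float = 0.1
    iti_s: float = 1.25
    lead_s: float = 4.0
    inversion_amp_delta: Mapping[str, float] = field(
        default_factory=lambda: {"P400": 1.5}
    )
    seed: int = 0

    def __post_init__(self):
        for p in (self.artifact_rate_amp, self.artifact_rate_flat, self.gaze_gap_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.n_sessions < 2:
            raise ValueError("need at least 2 sessions for reliability use")
        object.__setattr__(self, "inversion_amp_delta", dict(self.inversion_amp_delta))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth logged for one simulated session."""

    subject: int
    session: int
    component_latency: Mapping[str, float]  # session-level truth, ms
    component_amp: Mapping[str, float]  # session-level truth, µV (magnitude)
    amp_artifacts: tuple  # (trial_id, channel_label) pairs
    flat_channels: tuple  # channel labels dead for the whole session
    conditions: tuple  # per-trial condition labels in onset order
    seed: int


# ---------------------------------------------------------------------------
# kernels


def erp_kernel(spec: ComponentSpec, latency: float, amp: float, time_axis_ms) -> np.ndarray:
    """Gaussian component bump evaluated on ``time_axis_ms`` (ms), in µV.

    ``polarity * amp * exp(-(t - latency)^2 / (2 width^2))``; negligible
    (< 4e-4 of the peak) beyond 4 widths from the latency.
    """
    t = np.asarray(time_axis_ms, dtype=float)
    return spec.polarity * amp * np.exp(-((t - latency) ** 2) / (2.0 * spec.width**2))


_CONDITION_COMPONENTS = {
    "checkerboard": ("P1",),
    "face_upright": ("N290", "P400"),
    "face_inverted": ("N290", "P400"),
    "animal_upright": ("N290", "P400"),
    "animal_inverted": ("N290", "P400"),
}


def kernel_sum(
    components: Sequence[ComponentSpec],
    condition: str,
    truth: TruthRecord,
    time_axis_ms,
    channel: str,
    inversion_amp_delta: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Noise-free epoch truth for one channel of one trial (µV).

    The independent oracle used by tests: the same expression the
    simulator adds into the continuous record.
    """
    inversion_amp_delta = inversion_amp_delta or {}
    out = np.zeros(len(np.atleast_1d(time_axis_ms)), dtype=float)
    by_name = {c.name: c for c in components}
    for name in _CONDITION_COMPONENTS.get(condition, ()):
        spec = by_name.get(name)
        if spec is None or channel not in spec.channels:
            continue
        amp = truth.component_amp[name]
        if condition.endswith("_inverted"):
            amp = amp + inversion_amp_delta.get(name, 0.0)
        out += erp_kernel(spec, truth.component_latency[name], amp, time_axis_ms)
    return out


# ---------------------------------------------------------------------------
# noise


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise of length ``n`` via spectral shaping."""
    n_freq = n // 2 + 1
    spectrum = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    f = np.fft.rfftfreq(n)
    scale = np.zeros(n_freq)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


# ---------------------------------------------------------------------------
# sessions


def _draw_subject_latents(
    components: Sequence[ComponentSpec], rng: np.random.Generator
) -> dict:
    out = {}
    for c in components:
        out[c.name] = (
            c.mu_latency + c.sd_latency_between * rng.standard_normal(),
            c.mu_amp + c.sd_amp_between * rng.standard_normal(),
        )
    return out


def simulate_session(
    cohort: CohortSpec,
    subject_truth: Mapping[str, tuple],
    session_idx: int,
    seed: int,
    components: Sequence[ComponentSpec] = DEFAULT_COMPONENTS,
    subject: int = 0,
) -> tuple:
    """Simulate one session for one subject.

    ``subject_truth`` maps component name to the subject-level
    ``(latency, amp)`` latents; session-level truth adds within-subject
    deviations drawn here. Returns ``(Recording, EventList, GazeStream,
    TruthRecord)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # session-level truth
    lat = {}
    amp = {}
    for c in components:
        lat0, amp0 = subject_truth[c.name]
        lat[c.name] = lat0 + c.sd_latency_within * rng.standard_normal()
        amp[c.name] = amp0 + c.sd_amp_within * rng.standard_normal()

    # trial order: shuffled mix of the three task conditions
    conditions = (
        ["checkerboard"] * cohort.n_checkerboard
        + ["face_upright"] * cohort.n_face_upright
        + ["face_inverted"] * cohort.n_face_inverted
    )
    rng.shuffle(conditions)
    n_trials = len(conditions)

    n_samples = int(round((2 * cohort.lead_s + n_trials * cohort.iti_s) * FS))
    onsets = (cohort.lead_s + cohort.iti_s * np.arange(n_trials)) * FS
    onsets = np.round(onsets).astype(int)
    trial_ids = tuple(range(n_trials))

    t_cont = np.arange(n_samples) / FS
    data = np.empty((len(DEFAULT_CHANNELS), n_samples))
    background = BACKGROUND_AMP_UV * np.sin(2 * np.pi * BACKGROUND_FREQ_HZ * t_cont)
    for i in range(len(DEFAULT_CHANNELS)):
        noise = (
            cohort.noise_sd * pink_noise(n_samples, cohort.pink_exponent, rng)
            if cohort.noise_sd > 0
            else 0.0
        )
        data[i] = background + noise

    # component kernels, rendered into the continuous record around each onset
    epoch_rel = np.arange(-int(0.1 * FS), int(0.7 * FS))  # generous support
    epoch_ms = epoch_rel / FS * 1000.0
    truth_stub = TruthRecord(
        subject, session_idx, lat, amp, (), (), tuple(conditions), seed
    )
    for k, onset in enumerate(onsets):
        idx = onset + epoch_rel
        for ci, ch in enumerate(DEFAULT_CHANNELS):
            wave = kernel_sum(
                components,
                conditions[k],
                truth_stub,
                epoch_ms,
                ch,
                cohort.inversion_amp_delta,
            )
            if np.any(wave):
                data[ci, idx] += wave

    # high-amplitude artifacts: one per (trial, channel) draw, a 250 µV bump
    amp_artifacts = []
    if cohort.artifact_rate_amp > 0:
        hits = rng.random((n_trials, len(DEFAULT_CHANNELS))) < cohort.artifact_rate_amp
        for k, ci in zip(*np.nonzero(hits)):
            center_ms = rng.uniform(100.0, 400.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            bump = sign * 250.0 * np.exp(-((epoch_ms - center_ms) ** 2) / (2 * 40.0**2))
            data[ci, onsets[k] + epoch_rel] += bump
            amp_artifacts.append((int(k), DEFAULT_CHANNELS[ci]))

    # flat channels: electrode dead for the whole session
    flat_channels = []
    if cohort.artifact_rate_flat > 0:
        for ci, ch in enumerate(DEFAULT_CHANNELS):
            if rng.random() < cohort.artifact_rate_flat:
                data[ci] = 0.0
                flat_channels.append(ch)
                amp_artifacts = [(k, c) for (k, c) in amp_artifacts if c != ch]

    rec = Recording(data=data, fs=FS, channels=DEFAULT_CHANNELS)
    events = EventList(onsets=onsets, conditions=tuple(conditions), trial_ids=trial_ids)
    gaze = _simulate_gaze(n_samples / FS, cohort.gaze_gap_rate, rng)
    truth = TruthRecord(
        subject=subject,
        session=session_idx,
        component_latency=lat,
        component_amp=amp,
        amp_artifacts=tuple(amp_artifacts),
        flat_channels=tuple(flat_channels),
        conditions=tuple(conditions),
        seed=seed,
    )
    return rec, events, gaze, truth


def _simulate_gaze(
    duration_s: float, gap_rate: float, rng: np.random.Generator, fs_gaze: float = 60.0
) -> GazeStream:
    """Gaze at 60 Hz with alternating valid/invalid runs of geometric length.

    Mean valid run 2 s; mean invalid run chosen so the long-run invalid
    fraction equals ``gap_rate``, which yields a mix of short
    (interpolatable, <=150 ms) and long gaps.
    """
    n = int(round(duration_s * fs_gaze))
    times = np.arange(n) / fs_gaze
    valid = np.ones(n, dtype=bool)
    if gap_rate > 0:
        mean_valid = 2.0 * fs_gaze
        mean_invalid = max(gap_rate / (1 - gap_rate) * mean_valid, 1.0)
        i = 0
        state = rng.random() > gap_rate
        while i < n:
            mean_run = mean_valid if state else mean_invalid
            run = int(rng.geometric(min(1.0, 1.0 / mean_run)))
            valid[i : i + run] = state
            i += run
            state = not state
    x = np.where(valid, 960.0 + 30.0 * rng.standard_normal(n), np.nan)
    y = np.where(valid, 540.0 + 30.0 * rng.standard_normal(n), np.nan)
    return GazeStream(times=times, x=x, y=y, valid=valid)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortData:
    """Lazy two-session cohort: sessions are materialized on demand.

    ``truth_table`` holds the session-level latent parameters per subject;
    ``true_icc`` the analytic ICC implied by the component variance model.
    """

    cohort: CohortSpec
    components: tuple
    subject_latents: tuple  # per subject: {component: (latency, amp)}
    session_seeds: tuple  # [subject][session] -> int
    truth_table: pd.DataFrame
    true_icc: Mapping[str, float]

    def session(self, subject: int, session_idx: int):
        """Materialize (Recording, EventList, GazeStream, TruthRecord)."""
        return simulate_session(
            self.cohort,
            self.subject_latents[subject],
            session_idx,
            self.session_seeds[subject][session_idx],
            self.components,
            subject=subject,
        )


def simulate_cohort(
    cohort: CohortSpec,
    components: Sequence[ComponentSpec] = DEFAULT_COMPONENTS,
    seed: int | None = None,
) -> CohortData:
    """Draw subject latents and per-session seeds for a paired-session cohort."""
    if seed is None:
        seed = cohort.seed
    master = np.random.SeedSequence(seed)
    latent_rng = np.random.default_rng(master.spawn(1)[0])
    subject_latents = tuple(
        _draw_subject_latents(components, latent_rng) for _ in range(cohort.n_subjects)
    )
    session_seeds = tuple(
        tuple(
            int(np.random.SeedSequence((seed, subj, sess, 7)).generate_state(1)[0] % (2**31))
            for sess in range(cohort.n_sessions)
        )
        for subj in range(cohort.n_subjects)
    )

    rows = []
    for subj, latents in enumerate(subject_latents):
        for comp in components:
            lat0, amp0 = latents[comp.name]
            rows.append(
                {
                    "subject": subj,
                    "component": comp.name,
                    "latency_subject": lat0,
                    "amp_subject": amp0,
                }
            )
    truth_table = pd.DataFrame(rows)

    true_icc = {}
    for comp in components:
        true_icc[f"{comp.name}_latency"] = comp.true_icc_latency()
        true_icc[f"{comp.name}_amp"] = comp.true_icc_amp()

    return CohortData(
        cohort=cohort,
        components=tuple(components),
        subject_latents=subject_latents,
        session_seeds=session_seeds,
        truth_table=truth_table,
        true_icc=true_icc,
    )


def simulate_score_matrix(
    n_subjects: int, true_icc: float, rng: np.random.Generator, n_sessions: int = 2
) -> np.ndarray:
    """Subject-by-session score matrix from the latent variance model.

    Unit total variance split as ``true_icc`` between subjects and
    ``1 - true_icc`` within; the consistency ICC of the generating process
    is exactly ``true_icc``. This is the same between/within draw the
    cohort simulator uses for component parameters, without rendering EEG.
    """
    if not 0.0 <= true_icc <= 1.0:
        raise ValueError("true_icc must be in [0, 1]")
    subj = np.sqrt(true_icc) * rng.standard_normal((n_subjects, 1))
    noise = np.sqrt(1.0 - true_icc) * rng.standard_normal((n_subjects, n_sessions))
    return subj + noise
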