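import numpy as np
import pytest

from erpkit.preprocess import TrialSet
from erpkit.synthetic_data import CohortSpec, DEFAULT_COMPONENTS, simulate_cohort

FS = 500.0
TIME_MS = np.arange(-50, 301) / FS * 1000.0  # -100..600 ms epoch


def gaussian_bump(time_ms, latency, amp, width, polarity=1):
    """Independent closed-form component truth used as a test oracle."""
    t = np.asarray(time_ms, dtype=float)
    return polarity * amp * np.exp(-((t - latency) ** 2) / (2.0 * width**2))


def make_trialset(trials, conditions=None, channels=None, fs=FS):
    """Build a TrialSet directly from an (n, ch, T) array (no preprocessing)."""
    trials = np.asarray(trials, dtype=float)
    n, n_ch, T = trials.shape
    if channels is None:
        channels = ("FPz", "Fz", "Cz", "Oz", "C3", "C4", "P7", "P8")[:n_ch]
    if conditions is None:
        conditions = ("checkerboard",) * n
    time_ms = np.arange(-T // 2 + 1, T - T // 2 + 1) if T != 351 else TIME_MS
    if T == 351:
        time_ms = TIME_MS
    else:
        time_ms = np.arange(T) / fs * 1000.0
    return TrialSet(
        trials=trials,
        time_ms=time_ms,
        fs=fs,
        channels=tuple(channels),
        conditions=tuple(conditions),
        trial_ids=tuple(range(n)),
    )


@pytest.fixture(scope="session")
def noiseless_session():
    """One noiseless, artifact-free simulated session with its ground truth.

    Shared by the feature-recovery tests; expensive enough to build once.
    """
    spec = CohortSpec(
        n_subjects=1,
        noise_sd=0.0,
        artifact_rate_amp=0.0,
        artifact_rate_flat=0.0,
        gaze_gap_rate=0.0,
        seed=11,
    )
    cohort = simulate_cohort(spec, DEFAULT_COMPONENTS, seed=11)
    rec, events, gaze, truth = cohort.session(0, 0)
    return rec, events, gaze, truth


@pytest.fixture(scope="session")
def noiseless_trialsets(noiseless_session):
    from erpkit.preprocess import preprocess_session

    rec, events, _, truth = noiseless_session
    return (
        {
            fam: preprocess_session(rec, events, fam)
            for fam in ("checkerboard", "faces")
        },
        truth,
    )
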