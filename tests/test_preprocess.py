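import numpy as np
import pytest

from conftest import make_trialset
from erpkit import preprocess as pp
from erpkit.io_formats import DEFAULT_CHANNELS, EventList, Recording

FS = 500.0


def _recording(n_samples=30000, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return Recording(
        data=scale * rng.standard_normal((8, n_samples)),
        fs=FS,
        channels=DEFAULT_CHANNELS,
    )


def _events(onsets, condition="checkerboard"):
    onsets = np.asarray(onsets)
    return EventList(
        onsets=onsets,
        conditions=(condition,) * len(onsets),
        trial_ids=tuple(range(len(onsets))),
    )


class TestSegment:
    def test_epoch_length_and_count(self):
        rec = _recording(120000)
        onsets = 2000 + 1500 * np.arange(72)
        ts = pp.segment(rec, _events(onsets))
        assert len(ts) == 72
        assert ts.trials.shape == (72, 8, 351)  # (600-(-100))/2 + 1 samples
        assert ts.time_ms[0] == pytest.approx(-100.0)
        assert ts.time_ms[-1] == pytest.approx(600.0)
        # t=0 aligned to the onset sample
        k0 = np.argmin(np.abs(ts.time_ms))
        np.testing.assert_allclose(ts.trials[0, :, k0], rec.data[:, onsets[0]])

    def test_empty_eventlist(self):
        ts = pp.segment(_recording(5000), _events([]))
        assert len(ts) == 0

    def test_padding_unavailable_reflects_and_logs(self):
        rec = _recording(10000)
        ts = pp.segment(rec, _events([100]))  # window fits, 3 s pad does not
        assert not ts.excluded[0]
        assert ts.reflect_padded[0]
        assert ts.padded.shape[-1] == 351 + 2 * 1500

    def test_onset_outside_recording_excluded_as_edge(self):
        rec = _recording(10000)
        ts = pp.segment(rec, _events([10, 5000]))
        assert ts.excluded[0] and ts.excl_reason[0] == "edge"
        assert not ts.excluded[1]


class TestBandpass:
    @staticmethod
    def _tapered_sine(f, n_s=10.0, amp=100.0):
        """Sine with smoothly tapered edges: its spectrum stays near f, so
        the measurement is not contaminated by the low-frequency transient
        an abrupt onset would inject into the 0.1 Hz high-pass."""
        import scipy.signal

        t = np.arange(int(n_s * FS)) / FS
        return amp * np.sin(2 * np.pi * f * t) * scipy.signal.windows.tukey(len(t), 0.4)

    @staticmethod
    def _component_amp(y, f):
        mid = slice(len(y) // 4, 3 * len(y) // 4)
        t = np.arange(len(y))[mid] / FS
        seg = y[mid]
        return 2.0 * np.abs(np.mean(seg * np.exp(-2j * np.pi * f * t)))

    def test_stopband_attenuation_matches_design_at_50hz(self):
        """Measured 50 Hz attenuation agrees with the two-pass transfer
        function of the designed filter within 1 dB (and exceeds 26 dB)."""
        x = self._tapered_sine(50.0)
        y = pp.bandpass_filter(x, FS)
        measured = self._component_amp(y, 50.0) / self._component_amp(x, 50.0)
        designed = pp.bandpass_gain(50.0, FS)
        assert 20 * np.log10(measured) == pytest.approx(20 * np.log10(designed), abs=1.0)
        assert measured < 0.15  # the shallow band-pass skirt alone

    def test_pipeline_removes_stationary_line_noise(self):
        """The band-pass skirt is shallow at 50 Hz (which is why the line
        filter exists); through the full padded-segment pipeline the two
        stages remove stationary 80 µV line noise to well under 1 µV."""
        n = 30000
        t = np.arange(n) / FS
        rng = np.random.default_rng(0)
        data = 80 * np.sin(2 * np.pi * 50 * t)[None, :] + 5.0 * rng.standard_normal(
            (8, n)
        )
        rec = Recording(data=data, fs=FS, channels=DEFAULT_CHANNELS)
        ts = pp.preprocess_session(rec, _events([5000, 10000, 15000]), "checkerboard")
        oz = ts.channel_index("Oz")
        tt = ts.time_ms / 1000.0
        for k in range(len(ts)):
            residual = 2 * np.abs(np.mean(ts.trials[k, oz] * np.exp(-2j * np.pi * 50 * tt)))
            assert residual < 1.0

    def test_passband_preserves_10hz(self):
        x = self._tapered_sine(10.0)
        y = pp.bandpass_filter(x, FS)
        ratio = self._component_amp(y, 10.0) / self._component_amp(x, 10.0)
        assert ratio == pytest.approx(1.0, abs=0.05)
        assert ratio == pytest.approx(pp.bandpass_gain(10.0, FS), abs=0.01)

    def test_dc_attenuated(self):
        x = np.full(5000, 42.0)
        y = pp.bandpass_filter(x, FS)
        assert np.sqrt(np.mean(y**2)) < 0.5

    def test_nonfinite_rejected(self):
        x = np.zeros(1000)
        x[5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pp.bandpass_filter(x, FS)


class TestDftLineFilter:
    def test_exact_cancellation_integer_cycles(self):
        t = np.arange(int(2 * FS)) / FS  # 100 integer cycles of 50 Hz
        for phase, amp in [(0.0, 80.0), (1.2, 15.0)]:
            x = amp * np.sin(2 * np.pi * 50.0 * t + phase)
            y = pp.dft_line_filter(x, FS)
            assert np.abs(y).max() < 1e-6

    def test_orthogonal_signal_untouched(self):
        t = np.arange(int(2 * FS)) / FS
        x = 30.0 * np.sin(2 * np.pi * 10.0 * t)
        y = pp.dft_line_filter(x, FS)
        np.testing.assert_allclose(y, x, atol=1e-6)

    def test_mixture_removed_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        t = np.arange(int(2 * FS)) / FS
        x = (
            20.0 * np.sin(2 * np.pi * 50.0 * t + 0.3)
            + 7.0 * np.cos(2 * np.pi * 100.0 * t)
            + rng.standard_normal(len(t))
        )
        y = pp.dft_line_filter(x, FS)
        # independent oracle: explicit normal equations for the LS fit
        cols = []
        for f in (50.0, 100.0, 150.0):
            cols += [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
        X = np.stack(cols, axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ x)
        np.testing.assert_allclose(y, x - X @ beta, atol=1e-9)
        # both line components gone
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(len(t), 1 / FS)
        assert spec[np.argmin(np.abs(freqs - 50.0))] < 1e-6 * len(t)
        assert spec[np.argmin(np.abs(freqs - 100.0))] < 1e-6 * len(t)


class TestBaseline:
    time_ms = np.arange(-50, 301) / FS * 1000.0

    def test_constant_goes_to_zero(self):
        y = pp.baseline_correct(np.full(351, 7.0), self.time_ms)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_shift_by_baseline_mean(self):
        x = np.zeros(351)
        x[:51] = 3.0  # baseline window is the first 51 samples (-100..0 ms)
        y = pp.baseline_correct(x, self.time_ms)
        np.testing.assert_allclose(y, x - 3.0, atol=1e-12)
        assert abs(y[: 51].mean()) < 1e-12
        # idempotence on an already zero-mean baseline
        np.testing.assert_allclose(pp.baseline_correct(y, self.time_ms), y, atol=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            pp.baseline_correct(np.zeros(351), self.time_ms, window_ms=(-500, -400))


class TestArtifactRules:
    def test_amplitude_and_flat_flags_with_boundaries(self):
        trials = np.ones((3, 2, 351))
        trials[0, 0, 10] = 151.0  # amplitude artifact
        trials[1, 0, :] = 0.0  # flat
        trials[2, 0, 20] = 150.0  # exactly at threshold: retained
        flags, flat, amp = pp.flag_artifacts(trials)
        assert amp[0, 0] and not flat[0, 0]
        assert flat[1, 0] and not amp[1, 0]
        assert not flags[2, 0]
        assert not flags[:, 1].any()

    def test_flag_independent_of_trial_and_channel_order(self):
        rng = np.random.default_rng(1)
        trials = rng.standard_normal((6, 4, 351)) * 60
        flags, _, _ = pp.flag_artifacts(trials)
        perm_t = rng.permutation(6)
        perm_c = rng.permutation(4)
        flags_p, _, _ = pp.flag_artifacts(trials[perm_t][:, perm_c])
        np.testing.assert_array_equal(flags_p, flags[perm_t][:, perm_c])

    @pytest.mark.parametrize("n_flagged,expected", [(80, True), (79, False), (0, False)])
    def test_bad_channel_80_percent_rule(self, n_flagged, expected):
        flags = np.zeros((100, 1), dtype=bool)
        flags[:n_flagged, 0] = True
        assert pp.exclude_bad_channels(flags)[0] == expected


class TestRereference:
    def _ts(self):
        ts = make_trialset(np.ones((3, 8, 351)))
        ts.flags = np.zeros((3, 8), dtype=bool)
        return ts

    def test_primary_reference_subtracted(self):
        ts = self._ts()
        ts.trials[0, ts.channel_index("Cz")] = 2.0
        pp.rereference(ts, pp.PreprocConfig())
        assert ts.reference_used[0] == "Cz"
        np.testing.assert_allclose(ts.trials[0, ts.channel_index("P7")], -1.0)

    def test_fallback_mean_c3_c4(self):
        ts = self._ts()
        ts.flags[1, ts.channel_index("Cz")] = True
        ts.trials[1, ts.channel_index("C3")] = 2.0  # mean(C3,C4) = 1.5
        pp.rereference(ts, pp.PreprocConfig())
        assert ts.reference_used[1] == "mean(C3,C4)"
        np.testing.assert_allclose(ts.trials[1, ts.channel_index("P7")], -0.5)

    def test_no_reference_excludes_trial(self):
        ts = self._ts()
        ts.flags[2, ts.channel_index("Cz")] = True
        ts.flags[2, ts.channel_index("C3")] = True
        pp.rereference(ts, pp.PreprocConfig())
        assert ts.excluded[2] and ts.excl_reason[2] == "no_reference"

    def test_missing_reference_channel_is_config_error(self):
        ts = make_trialset(np.ones((1, 2, 351)), channels=("P7", "P8"))
        ts.flags = np.zeros((1, 2), dtype=bool)
        with pytest.raises(ValueError, match="reference channel"):
            pp.rereference(ts, pp.PreprocConfig())


def build_planted_fixture():
    """10 face trials with hand-placed artifacts.

    Expected by manual enumeration:
      trial 0: P7 amp artifact (151)        -> excluded (artifact_P7)
      trial 1: P8 exactly +150              -> retained (strict 'exceeded')
      trial 2: Oz flat                      -> retained (faces ignore Oz)
      trial 3: Cz amp artifact              -> retained via mean(C3,C4)
      trial 4: Cz and C3 artifacts          -> excluded (no_reference)
      trial 5: clean                        -> retained (Cz)
      trial 6: P7 exactly -150              -> retained
      trial 7: P8 at 150.0001               -> excluded
      trial 8: clean                        -> retained
      trial 9: P7 flat                      -> excluded
      FPz carries artifacts in trials 0-7 (8/10 = 80%) -> bad channel
    """
    trials = np.ones((10, 8, 351))
    ch = {c: i for i, c in enumerate(("FPz", "Fz", "Cz", "Oz", "C3", "C4", "P7", "P8"))}
    trials[0, ch["P7"], 5] = 151.0
    trials[1, ch["P8"], 5] = 150.0
    trials[2, ch["Oz"], :] = 0.0
    trials[3, ch["Cz"], 5] = -151.0
    trials[4, ch["Cz"], 5] = -151.0
    trials[4, ch["C3"], 5] = 151.0
    trials[6, ch["P7"], 5] = -150.0
    trials[7, ch["P8"], 5] = 150.0001
    trials[9, ch["P7"], :] = 0.0
    trials[:8, ch["FPz"], 5] = 200.0
    expected_excluded = {0, 4, 7, 9}
    return trials, expected_excluded


class TestConditionRules:
    def test_planted_fixture_matches_manual_enumeration(self):
        trials, expected_excluded = build_planted_fixture()
        ts = make_trialset(trials, conditions=("face_upright",) * 10)
        cfg = pp.PreprocConfig()
        ts.flags, ts.flag_flat, ts.flag_amp = pp.flag_artifacts(ts.trials)
        bad = pp.exclude_bad_channels(ts.flags)
        ts.bad_channels = tuple(c for c, b in zip(ts.channels, bad) if b)
        assert ts.bad_channels == ("FPz",)
        pp.apply_condition_rules(ts, cfg, "faces")
        assert set(np.nonzero(ts.excluded)[0]) == expected_excluded
        assert ts.n_clean == 6
        assert ts.reference_used[3] == "mean(C3,C4)"
        assert ts.reference_used[5] == "Cz"

    def test_checkerboard_ignores_parietal_artifacts(self):
        trials = np.ones((2, 8, 351))
        trials[0, 6, 5] = 200.0  # P7 artifact
        trials[1, 3, 5] = 200.0  # Oz artifact
        ts = make_trialset(trials)
        ts.flags, ts.flag_flat, ts.flag_amp = pp.flag_artifacts(ts.trials)
        pp.apply_condition_rules(ts, pp.PreprocConfig(), "checkerboard")
        assert not ts.excluded[0]  # P7 flagged but Oz clean
        assert ts.excluded[1]

    def test_faces_and_or_rule(self):
        trials = np.ones((1, 8, 351))
        trials[0, 6, 5] = 200.0  # P7 only
        ts = make_trialset(trials, conditions=("face_upright",))
        ts.flags, ts.flag_flat, ts.flag_amp = pp.flag_artifacts(ts.trials)
        pp.apply_condition_rules(ts, pp.PreprocConfig(), "faces")
        assert ts.excluded[0]


class TestConfig:
    def test_nyquist_guard(self):
        cfg = pp.PreprocConfig(bp_hi=260.0)
        with pytest.raises(ValueError, match="Nyquist"):
            cfg.validate_for_fs(500.0)

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            pp.PreprocConfig(bp_lo=40.0, bp_hi=0.1)
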