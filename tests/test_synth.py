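"""The synthetic generator: noise classes, recipes, schedules, fixtures."""

import numpy as np
import pytest

from vigilscore import (
    DEFAULT_RECIPES,
    StateSchedule,
    check_recipe,
    colored_noise,
    default_schedule,
    inject_spindles,
    pac_signal,
    synth_recording,
)


class TestColoredNoise:
    def test_white_noise_has_no_lag_one_autocorrelation(self):
        x = colored_noise(0.0, 50000, seed=0)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.02

    def test_brown_noise_periodogram_slope_is_minus_two(self):
        x = colored_noise(2.0, 65536, fs=1.0, seed=1)
        f = np.fft.rfftfreq(x.size)
        p = np.abs(np.fft.rfft(x)) ** 2
        sel = (f > 0.001) & (f < 0.2)
        # bin-average the periodogram before the log-log fit
        nbins = 30
        edges = np.geomspace(0.001, 0.2, nbins + 1)
        fm, pm = [], []
        for a, b in zip(edges, edges[1:]):
            m = (f >= a) & (f < b)
            if m.any():
                fm.append(f[m].mean())
                pm.append(p[m].mean())
        slope = np.polyfit(np.log(fm), np.log(pm), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.2)

    def test_same_seed_reproduces_bitwise(self):
        assert np.array_equal(colored_noise(1.0, 1024, seed=7), colored_noise(1.0, 1024, seed=7))

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError):
            colored_noise(1.0, 8, seed=0)


class TestRecipes:
    @pytest.mark.parametrize("state", list(DEFAULT_RECIPES))
    def test_default_recipe_satisfies_its_own_rule(self, state):
        """Each state's generator must pass that state's band rule >= 95/100."""
        frac = check_recipe(state, DEFAULT_RECIPES[state], seed=0)
        assert frac >= 0.95

    def test_emg_tone_is_higher_awake_than_asleep(self):
        assert DEFAULT_RECIPES["a1"].emg_tone > 3 * DEFAULT_RECIPES["nREM1"].emg_tone

    def test_only_deeper_nrem_states_carry_spindles(self):
        rates = {s: r.spindle_rate for s, r in DEFAULT_RECIPES.items()}
        assert rates["nREM3"] > rates["nREM2"] > 0
        assert all(rates[s] == 0 for s in ("a1", "a2", "a3", "REM", "nREM1"))


class TestSchedule:
    def test_ground_truth_labels_follow_entries(self):
        sched = StateSchedule([("a1", 3.0), ("nREM1", 2.0)])
        assert sched.labels(1.0).labels == "aaamm"

    def test_total_duration_sums_entries(self):
        assert default_schedule(600.0).total_duration == pytest.approx(600.0)

    def test_csv_round_trip(self, tmp_path):
        sched = default_schedule(120.0)
        path = tmp_path / "sched.csv"
        sched.write_csv(path)
        assert StateSchedule.read_csv(path).entries == sched.entries

    def test_unknown_state_is_an_error(self):
        with pytest.raises(ValueError):
            StateSchedule([("hibernation", 10.0)])


class TestSynthRecording:
    def test_deterministic_under_fixed_seed(self):
        sched = StateSchedule([("a1", 10.0), ("nREM1", 10.0)])
        r1, t1 = synth_recording(sched, seed=3)
        r2, t2 = synth_recording(sched, seed=3)
        assert np.array_equal(r1.signal, r2.signal)
        assert t1.labels == t2.labels

    def test_sleep_only_schedule_keeps_muscle_tone_low(self):
        from vigilscore import detect_tone_changepoints, emg_summary

        rec_sleep, _ = synth_recording(StateSchedule([("nREM1", 60.0)]), seed=4)
        rec_wake, _ = synth_recording(StateSchedule([("a1", 60.0)]), seed=4)
        env_s = emg_summary(rec_sleep.pick("EMG"), rec_sleep.fs)
        env_w = emg_summary(rec_wake.pick("EMG"), rec_wake.fs)
        # tone contrast ~5x in amplitude -> ~25x in summed power
        assert env_w.values.mean() > 10 * env_s.values.mean()
        floor = env_w.values.mean() / 2
        segs = detect_tone_changepoints(env_s, noise_floor=floor)
        assert [st for _, _, st in segs.segments] == ["relaxed"]

    def test_shared_component_makes_channels_coherent_at_its_frequency(self):
        from vigilscore import coherence_profile

        rec, _ = synth_recording(
            StateSchedule([("a1", 60.0)]), seed=5, shared_freq=8.0, shared_amp=4.0
        )
        eeg = rec.pick("EEG")
        prof = coherence_profile(eeg[0], eeg[1], rec.fs)
        # each channel also carries its own independent recipe oscillations,
        # so coherence plateaus near 1 around the shared tone: localize the
        # peak to within half an octave rather than a single grid bin
        assert abs(np.log2(prof.peak_freq / 8.0)) <= 0.25
        assert prof.peak_value > 0.8
        sel = np.argmin(np.abs(prof.freqs - 8.0))
        assert prof.coherence[sel] > 0.9

    def test_noise_epochs_are_ground_truthed_as_noise_and_scored_as_noise(self):
        from vigilscore import score_recording

        rec, truth = synth_recording(
            StateSchedule([("a1", 30.0), ("nREM1", 30.0)]), seed=6, noise_epochs=(5, 40)
        )
        assert truth.labels[5] == "N" and truth.labels[40] == "N"
        labels = score_recording(rec)
        assert labels.labels[5] == "N" and labels.labels[40] == "N"


class TestFixtures:
    def test_pac_depth_zero_leaves_carrier_unmodulated(self):
        x = pac_signal(4.0, 40.0, 0.0, 4096, 256.0, seed=1, noise_amp=0.0)
        from scipy.signal import hilbert

        from vigilscore.pac import _bandpass

        env = np.abs(hilbert(_bandpass(x, 256.0, 34, 46)))
        inner = env[512:-512]
        assert inner.std() / inner.mean() < 0.1

    def test_inject_zero_amplitude_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4096)
        y = inject_spindles(x, 128.0, np.array([10.0]), amp=0.0)
        assert np.allclose(x, y)

    def test_overlapping_bursts_are_an_error(self):
        x = np.zeros(int(60 * 128))
        with pytest.raises(ValueError):
            inject_spindles(x, 128.0, np.array([10.0, 10.5]), dur=1.0)

    def test_burst_outside_signal_is_an_error(self):
        with pytest.raises(ValueError):
            inject_spindles(np.zeros(1280), 128.0, np.array([9.8]), dur=1.0)
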