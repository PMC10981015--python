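"""Filtering, epoching, baseline, rejection, averaging, window measures."""

import itertools

import numpy as np
import pytest
from scipy import signal

from sfgsim.cohort import EEG_CHANNELS, build_session_schedule, \
    generate_session_eeg, young_template
from sfgsim.erp import (ContinuousEEG, ORN_WINDOWS_MS, P400_WINDOW_MS,
                        average_evoked, bandpass_filter, baseline_correct,
                        extract_epochs, permutation_paired_ttest,
                        reject_artifacts, window_measures)
from sfgsim.errors import (EmptyConditionError, InvalidParameterError)

from conftest import make_profile


def _eeg(data, events=None, ch_names=None, sfreq=1000.0):
    n_ch = data.shape[0]
    return ContinuousEEG(ch_names=ch_names or [f"ch{i}" for i in range(n_ch)],
                         sfreq=sfreq, data=data, events=events or [])


def _event(sample, condition="LN", has_figure=True, correct=True):
    return {"sample": sample, "condition": condition,
            "has_figure": has_figure, "correct": correct}


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(30000) / 1000.0
        x = np.sin(2 * np.pi * 40 * t)[None, :]
        out = bandpass_filter(_eeg(x), numtaps=4001)
        mid = out.data[0, 10000:20000]
        assert np.abs(mid).max() == pytest.approx(1.0, abs=0.01)

    def test_dc_removed(self):
        x = np.full((1, 30000), 7.0)
        out = bandpass_filter(_eeg(x), numtaps=4001)
        assert np.abs(out.data[0, 10000:20000]).max() < 0.05

    def test_slow_drift_attenuated_in_frequency_response(self):
        # evaluate the designed default filter directly
        taps = signal.firwin(18113, [0.5, 80.0], window=("kaiser", 5.65326),
                             pass_zero=False, fs=1000.0)
        for f, bound_db in ((0.05, -20.0), (40.0, -0.1)):
            w, h = signal.freqz(taps, worN=[2 * np.pi * f / 1000.0])
            gain_db = 20 * np.log10(np.abs(h[0]) + 1e-12)
            if bound_db < -1:
                assert gain_db <= bound_db
            else:
                assert abs(gain_db) <= abs(bound_db)

    def test_filter_longer_than_record_raises(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(_eeg(np.zeros((1, 1000))), numtaps=4001)

    def test_bad_band_raises(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(_eeg(np.zeros((1, 30000))), low=80, high=0.5)


class TestExtractEpochs:
    def test_sample_window_convention(self):
        data = np.arange(20000, dtype=float)[None, :]
        eeg = _eeg(data, [_event(10000)])
        ep = extract_epochs(eeg)
        assert ep.data.shape == (1, 1, 3100)
        assert ep.data[0, 0, 0] == 9200  # onset - 800 ms
        assert ep.data[0, 0, -1] == 12299  # half-open end
        assert ep.times_ms[0] == -800.0
        assert ep.times_ms[-1] == 2299.0

    def test_incorrect_trials_excluded(self):
        data = np.zeros((1, 20000))
        eeg = _eeg(data, [_event(10000, correct=False),
                          _event(12000, correct=True)])
        ep = extract_epochs(eeg)
        assert len(ep.meta) == 1

    def test_edge_event_skipped_with_warning(self):
        eeg = _eeg(np.zeros((1, 5000)), [_event(400), _event(2500)])
        with pytest.warns(UserWarning):
            ep = extract_epochs(eeg)
        assert len(ep.meta) == 0 or len(ep.meta) == 1

    def test_event_outside_record_rejected_at_construction(self):
        with pytest.raises(InvalidParameterError):
            _eeg(np.zeros((1, 100)), [_event(100)])


class TestBaseline:
    def _epochs(self, data, events):
        return extract_epochs(_eeg(data, events))

    def test_constant_epoch_becomes_zero(self):
        ep = self._epochs(np.full((2, 20000), 7.0), [_event(10000)])
        out = baseline_correct(ep)
        assert np.abs(out.data).max() < 1e-10

    def test_zero_mean_baseline_unchanged(self):
        data = np.zeros((1, 20000))
        data[0, 10000:] = 5.0  # post-onset step; baseline window untouched
        out = baseline_correct(self._epochs(data, [_event(10000)]))
        assert out.data[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.data[0, 0, -1] == pytest.approx(5.0)

    def test_linear_trend_intercept_shifted(self):
        slope = 0.01
        data = (slope * np.arange(20000, dtype=float))[None, :]
        out = baseline_correct(self._epochs(data, [_event(10000)]))
        # ramp mean over [-800, 0) sits at -400.5 ms relative to onset
        expected_first = slope * (-800 - (-400.5))
        assert out.data[0, 0, 0] == pytest.approx(expected_first, abs=1e-9)
        diffs = np.diff(out.data[0, 0])
        assert np.allclose(diffs, slope)  # trend preserved

    def test_baseline_mean_zero_after_correction(self, rng):
        data = rng.normal(0, 10, (3, 20000))
        out = baseline_correct(self._epochs(data, [_event(10000),
                                                   _event(14000)]))
        mask = out.times_ms < 0
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-10


class TestRejection:
    def _epochs_with_amplitudes(self, amps):
        data = np.zeros((len(amps), 1, 3100))
        for i, a in enumerate(amps):
            data[i, 0, 1500] = a
        ep = extract_epochs(_eeg(np.zeros((1, 4000)), [_event(1000)]))
        ep.data = data
        import pandas as pd
        ep.meta = pd.DataFrame({"condition": ["LN"] * len(amps),
                                "has_figure": [True] * len(amps),
                                "accepted": [True] * len(amps)})
        return ep

    def test_spike_above_threshold_rejected(self):
        ep = reject_artifacts(self._epochs_with_amplitudes([150.0]), 100.0)
        assert not ep.accepted().any()

    def test_bounded_epochs_kept(self):
        ep = reject_artifacts(self._epochs_with_amplitudes([50.0, -50.0]),
                              100.0)
        assert ep.accepted().all()

    def test_rejected_count_matches_bruteforce_scan(self, rng):
        amps = rng.uniform(-200, 200, 40)
        ep = self._epochs_with_amplitudes(amps)
        out = reject_artifacts(ep, 100.0)
        brute = np.array([np.max(np.abs(ep.data[i])) > 100.0
                          for i in range(len(amps))])
        np.testing.assert_array_equal(~out.accepted(), brute)

    def test_monotone_in_threshold(self, rng):
        amps = rng.uniform(-200, 200, 40)
        ep = self._epochs_with_amplitudes(amps)
        counts = [(~reject_artifacts(ep, thr).accepted()).sum()
                  for thr in (50, 100, 150, 250)]
        assert np.all(np.diff(counts) <= 0)

    def test_peak_to_peak_mode(self):
        ep = self._epochs_with_amplitudes([90.0])
        ep.data[0, 0, 1600] = -90.0  # range 180 < 200: kept
        assert reject_artifacts(ep, 100.0, mode="peak_to_peak").accepted()[0]
        ep.data[0, 0, 1600] = -150.0  # range 240 > 200: rejected
        assert not reject_artifacts(ep, 100.0,
                                    mode="peak_to_peak").accepted()[0]


class TestAveraging:
    def test_identical_epochs_average_to_one(self, rng):
        base = rng.normal(0, 1, (1, 3100))
        eeg = _eeg(np.zeros((1, 30000)),
                   [_event(5000), _event(15000), _event(25000)])
        ep = extract_epochs(eeg)
        ep.data = np.stack([base, base, base])
        ev = average_evoked(ep)
        np.testing.assert_allclose(ev.data, base)
        assert ev.n_epochs == 3

    def test_noise_shrinks_as_sqrt_n(self, rng):
        n = 100
        sigma = 5.0
        ep = extract_epochs(_eeg(np.zeros((1, 4000)), [_event(1000)]))
        ep.data = rng.normal(0, sigma, (n, 1, 3100))
        import pandas as pd
        ep.meta = pd.DataFrame({"condition": ["LN"] * n,
                                "has_figure": [True] * n,
                                "accepted": [True] * n})
        ev = average_evoked(ep)
        assert ev.data.std() == pytest.approx(sigma / np.sqrt(n), rel=0.15)

    def test_empty_condition_raises(self):
        ep = extract_epochs(_eeg(np.zeros((1, 5000)), [_event(2000)]))
        with pytest.raises(EmptyConditionError):
            average_evoked(ep, condition="HN")


class TestWindowMeasures:
    def _evoked(self, trace, ch="C3"):
        from sfgsim.erp import EvokedResponse
        times = np.arange(-800, 2300.0)
        return EvokedResponse(condition="LN", data=trace[None, :],
                              times_ms=times, ch_names=[ch], n_epochs=10)

    def test_constant_signal_mean(self):
        ev = self._evoked(np.full(3100, 5.0))
        m = window_measures(ev, "ORN", (250, 350), channels=("C3",))
        assert m.window_mean_uv["C3"] == pytest.approx(5.0)

    def test_negative_gaussian_peak_latency(self):
        times = np.arange(-800, 2300.0)
        trace = -3.0 * np.exp(-0.5 * ((times - 300) / 34.0) ** 2)
        ev = self._evoked(trace)
        m = window_measures(ev, "ORN", (250, 350), channels=("C3",))
        assert m.peak_latency_ms["C3"] == pytest.approx(300.0, abs=1.0)

    def test_latency_invariant_to_amplitude_scaling(self):
        times = np.arange(-800, 2300.0)
        trace = -np.exp(-0.5 * ((times - 310) / 40.0) ** 2)
        lat1 = window_measures(self._evoked(trace), "ORN", (250, 350),
                               channels=("C3",)).peak_latency_ms["C3"]
        lat2 = window_measures(self._evoked(7.3 * trace), "ORN", (250, 350),
                               channels=("C3",)).peak_latency_ms["C3"]
        assert lat1 == lat2

    def test_p400_uses_positive_extremum(self):
        times = np.arange(-800, 2300.0)
        trace = (4.0 * np.exp(-0.5 * ((times - 750) / 64.0) ** 2)
                 - 6.0 * np.exp(-0.5 * ((times - 700) / 20.0) ** 2))
        ev = self._evoked(trace, ch="Pz")
        m = window_measures(ev, "P400", P400_WINDOW_MS, channels=("Pz",))
        assert m.peak_latency_ms["Pz"] == pytest.approx(760, abs=15)

    def test_window_outside_data_raises(self):
        ev = self._evoked(np.zeros(3100))
        with pytest.raises(InvalidParameterError):
            window_measures(ev, "ORN", (5000, 6000), channels=("C3",))


class TestZeroNoiseChain:
    def test_template_recovered_through_full_pipeline(self):
        """Template in, template out: filter, epoch, baseline, reject,
        average on a zero-noise session deviates from the injected ORN/P400
        by < 0.5 µV (small residual from the 0.5 Hz high-pass edge)."""
        rng = np.random.default_rng(8)
        tpl = young_template(noise_sd_uv=0.0, artifact_rate_per_min=0.0)
        profile = make_profile(template=tpl)
        trials = [{"condition": "LN", "has_figure": True, "correct": True}
                  for _ in range(8)]
        sched = build_session_schedule(trials, rng)
        data, events = generate_session_eeg(profile, sched, rng)
        eeg = bandpass_filter(_eeg(data, events,
                                   ch_names=list(EEG_CHANNELS)))
        ep = reject_artifacts(baseline_correct(extract_epochs(eeg)), 100.0)
        assert ep.accepted().all()
        ev = average_evoked(ep)
        times = ev.times_ms
        sigma = tpl.orn_width_ms / (2 * np.sqrt(2 * np.log(2)))
        expected = tpl.orn_amplitude_uv * np.exp(
            -0.5 * ((times - tpl.orn_latency_ms) / sigma) ** 2)
        # the P400 template does not project to C3 (parietal weights only)
        got = ev.data[ev.ch_names.index("C3")]
        w_c3 = tpl.orn_weights["C3"]
        assert np.max(np.abs(got - w_c3 * expected)) < 0.5
        m = window_measures(ev, "ORN", ORN_WINDOWS_MS["young"])
        assert m.peak_latency_ms["C3"] == pytest.approx(280.0, abs=2)


class TestPermutationTTest:
    def test_identical_samples_give_p_one(self):
        a = np.arange(8.0)
        res = permutation_paired_ttest(a, a, n_perm=500,
                                       rng=np.random.default_rng(0))
        assert res["p"] == 1.0
        assert res["degenerate"]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.8, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        d = a - b
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(8))
        count = 0
        for signs in itertools.product([-1.0, 1.0], repeat=8):
            fd = np.array(signs) * d
            t = fd.mean() / (fd.std(ddof=1) / np.sqrt(8))
            count += abs(t) >= abs(t_obs)
        p_exact = count / 256
        res = permutation_paired_ttest(a, b, n_perm=20000,
                                       rng=np.random.default_rng(10))
        assert res["p"] == pytest.approx(p_exact, abs=0.02)

    def test_large_shift_hits_p_floor(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 16) + 100.0
        b = rng.normal(0, 1, 16)
        res = permutation_paired_ttest(a, b, n_perm=1000,
                                       rng=np.random.default_rng(12))
        assert res["p"] == pytest.approx(1 / 1001)

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(13)
        from scipy import stats as sps
        ps = []
        for _ in range(1000):
            d = rng.normal(0, 1, 12)
            res = permutation_paired_ttest(d, np.zeros(12), n_perm=199,
                                           rng=rng)
            ps.append(res["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01
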