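"""Generator contracts: determinism, calibration, type invariants."""

import numpy as np
import pytest

from neurogut import (
    ContinuousRecording,
    EvokedSpec,
    GutSpec,
    band_power,
    gen_eeg,
    gen_gut,
    gen_hypnogram,
    gen_lfp_evoked,
    gen_spikes,
    gen_stim_times,
    multitaper_psd,
)


class TestHypnogramAndStims:
    def test_hypnogram_contiguous_in_order(self):
        hyp = gen_hypnogram([("WAKE", 600.0), ("SWS", 600.0)])
        assert hyp.span == (0.0, 1200.0)
        assert [s for *_, s in hyp.intervals] == ["WAKE", "SWS"]

    def test_empty_hypnogram(self):
        assert len(gen_hypnogram([])) == 0

    def test_alternating_boundaries(self):
        hyp = gen_hypnogram([("WAKE", 300.0)] * 2 + [("SWS", 300.0)] * 2)
        assert [iv[0] for iv in hyp.intervals] == [0.0, 300.0, 600.0, 900.0]

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            gen_hypnogram([("REM", 100.0)])

    def test_stim_times_seed_reproducible(self):
        hyp = gen_hypnogram([("WAKE", 1200.0)])
        a = gen_stim_times(hyp, (45, 60), seed=5)
        b = gen_stim_times(hyp, (45, 60), seed=5)
        np.testing.assert_array_equal(a.onsets, b.onsets)

    def test_stim_count_bounds(self):
        hyp = gen_hypnogram([("WAKE", 1200.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=9)
        assert 20 <= len(ev) <= 26
        assert np.all((ev.onsets > 0) & (ev.onsets < 1200))

    def test_degenerate_isi_is_periodic(self):
        hyp = gen_hypnogram([("WAKE", 600.0)])
        ev = gen_stim_times(hyp, (60, 60), seed=1)
        np.testing.assert_allclose(np.diff(ev.onsets), 60.0, atol=1e-9)

    def test_short_span_warns_and_empty(self):
        hyp = gen_hypnogram([("WAKE", 10.0)])
        with pytest.warns(UserWarning):
            ev = gen_stim_times(hyp, (45, 60), seed=1)
        assert len(ev) == 0


class TestDeterminism:
    def test_generators_bit_identical_for_same_seed(self):
        hyp = gen_hypnogram([("WAKE", 120.0), ("SWS", 120.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=3)
        spec = [EvokedSpec(state="SWS")]
        for gen in (
            lambda s: gen_eeg(hyp, seed=s).samples,
            lambda s: gen_lfp_evoked(hyp, ev, spec, seed=s).samples,
            lambda s: gen_spikes(hyp, ev, 10.0, spec, seed=s).times,
            lambda s: gen_gut(hyp, ev, GutSpec(), seed=s).samples,
        ):
            np.testing.assert_array_equal(gen(77), gen(77))
            assert not np.array_equal(gen(77), gen(78))


class TestLfpGenerator:
    def test_state_gating_keeps_wake_average_flat(self):
        hyp = gen_hypnogram([("WAKE", 600.0), ("SWS", 600.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=11)
        spec = [EvokedSpec(latency_s=0.1, amplitude=5.0, duration_s=0.2, state="SWS")]
        rec = gen_lfp_evoked(hyp, ev, spec, rate=1000.0, seed=11)
        from neurogut import extract_epochs, exclude_trials
        epochs = extract_epochs(rec, ev, (0.5, 0.54))
        kept, _ = exclude_trials(epochs, hyp, ev)
        wake = kept.by_state("WAKE")
        sws = kept.by_state("SWS")
        win = (kept.rel_time >= 0.05) & (kept.rel_time < 0.3)
        wake_amp = np.abs(wake.data[:, win].mean(axis=0)).max()
        sws_amp = np.abs(sws.data[:, win].mean(axis=0)).max()
        se = 1.0 / np.sqrt(wake.n_trials)
        assert wake_amp < 4 * se          # no response expressed in wake
        assert sws_amp > 5 * wake_amp     # strong response in sleep

    def test_zero_amplitude_matches_pure_noise(self):
        hyp = gen_hypnogram([("SWS", 200.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=13)
        spec0 = [EvokedSpec(amplitude=0.0, state="SWS")]
        a = gen_lfp_evoked(hyp, ev, spec0, seed=13)
        b = gen_lfp_evoked(hyp, ev, [], seed=13)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EvokedSpec(latency_s=0.01)
        with pytest.raises(ValueError):
            EvokedSpec(sign="oscillatory")


class TestSpikeGenerator:
    def test_homogeneous_count_within_poisson_bounds(self):
        hyp = gen_hypnogram([("WAKE", 1000.0)])
        train = gen_spikes(hyp, gen_stim_times(hyp, (45, 60), seed=1), 10.0, [], seed=42)
        expected = 10.0 * 1000.0
        assert abs(len(train) - expected) < 3 * np.sqrt(expected)

    def test_times_strictly_increasing_within_span(self):
        hyp = gen_hypnogram([("WAKE", 300.0), ("SWS", 300.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=2)
        train = gen_spikes(hyp, ev, {"WAKE": 5.0, "SWS": 15.0}, [], seed=2)
        assert np.all(np.diff(train.times) > 0)
        assert train.times[0] >= 0 and train.times[-1] <= 600.0

    def test_state_dependent_baseline_rates(self):
        hyp = gen_hypnogram([("WAKE", 500.0), ("SWS", 500.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=3)
        train = gen_spikes(hyp, ev, {"WAKE": 5.0, "SWS": 20.0}, [], seed=3)
        n_wake = np.sum(train.times < 500.0)
        n_sws = np.sum(train.times >= 500.0)
        assert abs(n_wake - 2500) < 3 * np.sqrt(2500)
        assert abs(n_sws - 10000) < 3 * np.sqrt(10000)

    def test_excitatory_bump_recovered_by_detector(self):
        from neurogut import spike_density, detect_response
        hyp = gen_hypnogram([("SWS", 1500.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=4)
        spec = [EvokedSpec(latency_s=0.12, amplitude=40.0, duration_s=0.2, state="SWS")]
        train = gen_spikes(hyp, ev, 10.0, spec, seed=4)
        curve = spike_density(train, ev)
        call = detect_response(curve)
        assert call.significant and call.sign == "excitatory"
        assert call.onset_latency == pytest.approx(0.12 + 0.04, abs=0.06)

    def test_near_silent_baseline_flagged_not_crashing(self):
        from neurogut import spike_density, detect_response
        hyp = gen_hypnogram([("SWS", 1000.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=5)
        train = gen_spikes(hyp, ev, 0.001, [], seed=5)
        curve = spike_density(train, ev)
        call = detect_response(curve)
        assert not call.significant


class TestGutGenerator:
    def test_no_bursts_band_power_at_noise_floor(self):
        hyp = gen_hypnogram([("SWS", 400.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=6)
        quiet = gen_gut(hyp, ev, GutSpec(burst_rate_per_min=0.0), seed=6)
        busy = gen_gut(hyp, ev, GutSpec(), seed=6)
        p_quiet = band_power(multitaper_psd(ContinuousRecording(quiet.samples, 100.0)), (3, 10))
        p_busy = band_power(multitaper_psd(ContinuousRecording(busy.samples, 100.0)), (3, 10))
        assert p_busy > 3 * p_quiet

    def test_slow_wave_energy_below_2hz(self):
        hyp = gen_hypnogram([("SWS", 400.0)])
        ev = gen_stim_times(hyp, (45, 60), seed=7)
        rec = gen_gut(hyp, ev, GutSpec(), seed=7)
        psd = multitaper_psd(ContinuousRecording(rec.samples, 100.0))
        low = band_power(psd, (0, 2))
        high = band_power(psd, (2, 50))
        assert low > 2 * high

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GutSpec(slow_wave_hz=3.0)
        with pytest.raises(ValueError):
            GutSpec(burst_band_hz=(1.0, 10.0))
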