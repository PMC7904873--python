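"""Multitaper PSD, band power, staging validation, disturbance test."""

import numpy as np
import pytest

from neurogut import (
    ContinuousRecording,
    EventSeries,
    InsufficientDataError,
    StateHypnogram,
    band_power,
    compare_states,
    disturbance_test,
    gen_eeg,
    gen_hypnogram,
    gen_stim_times,
    multitaper_psd,
)
from neurogut.vigilance import PsdEstimate


class TestMultitaperPsd:
    def test_sinusoid_peak_frequency(self):
        rate = 200.0
        t = np.arange(0, 10, 1 / rate)
        rec = ContinuousRecording(np.sin(2 * np.pi * 10 * t), rate)
        psd = multitaper_psd(rec)
        f_peak = psd.frequencies[np.argmax(psd.power)]
        assert abs(f_peak - 10.0) <= 3.0 / 10.0  # NW / segment length

    def test_parseval_white_noise(self):
        """Integrated density approximates the variance (50-seed average)."""
        rate = 200.0
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(int(10 * rate))
            psd = multitaper_psd(ContinuousRecording(x, rate))
            total = np.trapezoid(psd.power, psd.frequencies)
            ratios.append(total / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_amplitude_scaling_squares_power(self, rng):
        x = rng.standard_normal(2000)
        p1 = multitaper_psd(ContinuousRecording(x, 200.0))
        p3 = multitaper_psd(ContinuousRecording(3 * x, 200.0))
        np.testing.assert_allclose(p3.power, 9 * p1.power, rtol=1e-9)

    def test_dc_offset_invariance(self, rng):
        x = rng.standard_normal(2000)
        p0 = multitaper_psd(ContinuousRecording(x, 200.0))
        p5 = multitaper_psd(ContinuousRecording(x + 5.0, 200.0))
        np.testing.assert_allclose(p5.power, p0.power, atol=1e-9 * p0.power.max())

    def test_zero_signal_zero_psd(self):
        psd = multitaper_psd(ContinuousRecording(np.zeros(2000), 200.0))
        assert np.all(psd.power == 0)

    def test_taper_count_validated(self):
        rec = ContinuousRecording(np.zeros(2000), 200.0)
        with pytest.raises(ValueError):
            multitaper_psd(rec, nw=3, n_tapers=6)

    def test_agrees_with_mne_multitaper(self, rng):
        """Independent oracle: mne's multitaper PSD on the same segment."""
        mne = pytest.importorskip("mne")
        rate = 200.0
        x = rng.standard_normal(int(10 * rate))
        x -= x.mean()
        ours = multitaper_psd(ContinuousRecording(x, rate), nw=3, n_tapers=5)
        bw = 2 * 3.0 / 10.0  # full bandwidth in Hz for NW=3 over 10 s
        psd_mne, f_mne = mne.time_frequency.psd_array_multitaper(
            x[None, :], rate, bandwidth=bw, adaptive=False, low_bias=False,
            normalization="full", verbose="error"
        )
        ours_interp = np.interp(f_mne, ours.frequencies, ours.power)
        band_ours = np.trapezoid(ours_interp[(f_mne > 1) & (f_mne < 90)],
                                 f_mne[(f_mne > 1) & (f_mne < 90)])
        band_mne = np.trapezoid(psd_mne[0][(f_mne > 1) & (f_mne < 90)],
                                f_mne[(f_mne > 1) & (f_mne < 90)])
        assert band_ours == pytest.approx(band_mne, rel=0.05)


class TestBandPower:
    def test_zero_psd_zero_power(self):
        psd = PsdEstimate(np.linspace(0, 100, 201), np.zeros(201), 5, 3.0, 1.0)
        assert band_power(psd, (1, 4)) == 0.0

    def test_flat_density_rectangle(self):
        psd = PsdEstimate(np.linspace(0, 100, 201), np.full(201, 2.5), 5, 3.0, 1.0)
        assert band_power(psd, (1, 4)) == pytest.approx(7.5)

    def test_disjoint_bands_bounded_by_total(self, rng):
        p = np.abs(rng.standard_normal(201))
        psd = PsdEstimate(np.linspace(0, 100, 201), p, 5, 3.0, 1.0)
        total = band_power(psd, (0, 100))
        parts = band_power(psd, (1, 4)) + band_power(psd, (7, 14)) + band_power(psd, (30, 75))
        assert parts <= total + 1e-12

    def test_band_outside_grid_rejected(self):
        psd = PsdEstimate(np.linspace(0, 100, 201), np.ones(201), 5, 3.0, 1.0)
        with pytest.raises(ValueError):
            band_power(psd, (120, 140))


class TestGenEegCalibration:
    def test_sws_delta_gain_doubles_power_ratio_four(self):
        hyp = gen_hypnogram([("WAKE", 300.0), ("SWS", 300.0)])
        eeg = gen_eeg(hyp, seed=21)
        powers = {}
        for state, (t0, t1) in (("WAKE", (0, 300)), ("SWS", (300, 600))):
            seg = ContinuousRecording(
                eeg.samples[int(t0 * 200) : int(t1 * 200)], 200.0
            )
            powers[state] = band_power(multitaper_psd(seg), (1, 4))
        assert powers["SWS"] / powers["WAKE"] == pytest.approx(4.0, rel=0.2)

    def test_zero_gamma_gain_leaves_only_leakage(self):
        hyp = gen_hypnogram([("SWS", 300.0)])
        gains = {"WAKE": {"delta": 1, "spindles": 1, "gamma": 1},
                 "SWS": {"delta": 1, "spindles": 1, "gamma": 0.0}}
        eeg = gen_eeg(hyp, gains, seed=22)
        psd = multitaper_psd(ContinuousRecording(eeg.samples, 200.0))
        assert band_power(psd, (30, 75)) < 0.01 * band_power(psd, (1, 4))


class TestCompareStates:
    def test_state_gain_construction_recovered(self):
        hyp = gen_hypnogram([("WAKE", 300.0), ("SWS", 300.0)])
        eeg = gen_eeg(hyp, seed=31)  # defaults: delta/spindle x2, gamma x0.5 in SWS
        res = compare_states(eeg, hyp, window_s=10.0)
        assert res["delta"].direction == "sws_higher"
        assert res["spindles"].direction == "sws_higher"
        assert res["gamma"].direction == "wake_higher"
        assert all(r.p_value < 0.001 for r in res.values())

    def test_single_state_hypnogram_errors(self):
        hyp = gen_hypnogram([("SWS", 300.0)])
        eeg = gen_eeg(hyp, seed=32)
        with pytest.raises(InsufficientDataError):
            compare_states(eeg, hyp)

    def test_equal_gains_mostly_non_significant(self):
        gains = {"WAKE": {"delta": 1, "spindles": 1, "gamma": 1},
                 "SWS": {"delta": 1, "spindles": 1, "gamma": 1}}
        hyp = gen_hypnogram([("WAKE", 200.0), ("SWS", 200.0)])
        flat = 0
        for seed in range(20):
            eeg = gen_eeg(hyp, gains, seed=seed)
            res = compare_states(eeg, hyp, window_s=10.0)
            flat += all(r.direction == "none" for r in res.values())
        assert flat >= 15  # 3 bands at alpha=0.05: ~86% fully clean

    def test_direction_tracks_generator_gain_ordering(self):
        """Gain ratio >= 2 at 20 windows/state: direction recovered per band."""
        gains = {"WAKE": {"delta": 1.0, "spindles": 2.0, "gamma": 1.0},
                 "SWS": {"delta": 2.0, "spindles": 1.0, "gamma": 1.0}}
        hyp = gen_hypnogram([("WAKE", 200.0), ("SWS", 200.0)])
        for seed in (41, 42, 43):
            res = compare_states(gen_eeg(hyp, gains, seed=seed), hyp)
            assert res["delta"].direction == "sws_higher"
            assert res["spindles"].direction == "wake_higher"


class TestDisturbance:
    def _session(self, seed, gamma_boost=1.0):
        hyp = gen_hypnogram([("SWS", 700.0)])
        events = gen_stim_times(hyp, (45.0, 60.0), seed=seed)
        eeg = gen_eeg(hyp, seed=seed + 1)
        if gamma_boost != 1.0:
            rng = np.random.default_rng(seed + 2)
            from neurogut.synthetic_data import _band_noise
            extra = _band_noise(rng, eeg.n_samples, 200.0, (30.0, 75.0))
            t = eeg.times
            mask = np.zeros(eeg.n_samples, dtype=bool)
            for onset in events.onsets:
                mask |= (t > onset) & (t <= onset + 10.0)
            boosted = eeg.samples.copy()
            boosted[mask] += gamma_boost * extra[mask]
            eeg = ContinuousRecording(boosted, 200.0, channel="EEG")
        return eeg, events, hyp

    def test_stationary_eeg_no_awakening(self):
        eeg, events, hyp = self._session(51)
        verdict = disturbance_test(eeg, events, hyp)
        assert not verdict.awakening

    def test_injected_post_stimulus_gamma_detected(self):
        eeg, events, hyp = self._session(52, gamma_boost=1.5)
        verdict = disturbance_test(eeg, events, hyp)
        assert verdict.awakening
        assert verdict.band_direction["gamma"] == "increase"

    def test_five_events_insufficient(self):
        hyp = gen_hypnogram([("SWS", 300.0)])
        eeg = gen_eeg(hyp, seed=53)
        events = EventSeries(np.array([30.0, 80.0, 130.0, 180.0, 230.0]))
        with pytest.raises(InsufficientDataError):
            disturbance_test(eeg, events, hyp)

    def test_symmetry_swapping_pre_post(self):
        """Time-reversing the recording swaps pre/post: p preserved, direction flipped."""
        eeg, events, hyp = self._session(54, gamma_boost=1.5)
        fwd = disturbance_test(eeg, events, hyp)
        rev = ContinuousRecording(eeg.samples[::-1].copy(), eeg.rate, channel="EEG")
        span = hyp.span[1]
        rev_events = EventSeries(np.sort(span - events.onsets))
        bwd = disturbance_test(rev, rev_events, hyp)
        flip = {"increase": "decrease", "decrease": "increase", "none": "none"}
        for band in fwd.band_p:
            assert bwd.band_p[band] == pytest.approx(fwd.band_p[band], rel=0.05)
            assert bwd.band_direction[band] == flip[fwd.band_direction[band]]
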