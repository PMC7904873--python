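"""Spike-density estimation, the 3 SD / 2 SD / 30 ms criterion, classification."""

import numpy as np
import pytest

from neurogut import (
    EventSeries,
    RateCurve,
    ResponseCall,
    SpikeTrain,
    classify_cell,
    detect_response,
    spike_density,
    tabulate_cells,
)
from neurogut.spike_response import CellCategory

from conftest import make_events


class TestSpikeDensity:
    def test_empty_train_zero_curve_degenerate(self):
        curve = spike_density(SpikeTrain("u", []), make_events([10.0, 20.0]))
        assert np.all(curve.mean_rate == 0)
        assert curve.baseline_sd == 0.0

    def test_single_spike_peak_is_gaussian_peak(self):
        curve = spike_density(SpikeTrain("u", [10.2]), make_events([10.0]))
        peak = curve.mean_rate.max()
        t_peak = curve.rel_time[np.argmax(curve.mean_rate)]
        assert peak == pytest.approx(1 / (0.02 * np.sqrt(2 * np.pi)), rel=1e-3)
        assert t_peak == pytest.approx(0.2, abs=0.001)

    def test_kernel_mass_conserved_per_trial(self, rng):
        """Integrating a trial's curve recovers its spike count."""
        spikes = np.sort(rng.uniform(9.7, 10.3, 17))  # support inside window
        curve = spike_density(SpikeTrain("u", spikes), make_events([10.0]))
        mass = curve.trial_rates[0].sum() * 0.001
        assert mass == pytest.approx(17.0, abs=1e-6 * 17)

    def test_doubling_spikes_doubles_mean_curve(self, rng):
        s1 = np.sort(rng.uniform(9.5, 10.5, 30))
        ev2 = make_events([10.0, 110.0])
        curve1 = spike_density(SpikeTrain("u", s1), make_events([10.0]))
        curve2 = spike_density(SpikeTrain("u", np.sort(np.concatenate([s1, s1 + 100.0]))), ev2)
        np.testing.assert_allclose(curve2.mean_rate, curve1.mean_rate, atol=1e-9)
        assert curve2.trial_rates.sum() == pytest.approx(2 * curve1.trial_rates.sum())

    def test_rows_decompose_per_trial(self, rng):
        """Each row equals the single-event computation: relabeling-safe."""
        spikes = np.sort(rng.uniform(0, 100, 500))
        train = SpikeTrain("u", spikes)
        a = spike_density(train, make_events([10.0, 40.0, 70.0]))
        for row, onset in zip(a.trial_rates, (10.0, 40.0, 70.0)):
            single = spike_density(train, make_events([onset]))
            np.testing.assert_allclose(row, single.trial_rates[0], atol=1e-12)


def _curve_with_bump(amp_sd, start, dur, baseline=10.0, sd=1.5):
    """Constructed averaged curve: flat baseline plus a rectangular bump."""
    t = np.arange(-0.5, 0.5, 0.001)
    rate = np.full(t.size, baseline)
    rate[(t >= start) & (t < start + dur)] += amp_sd * sd
    return RateCurve(t, rate, rate[None, :], baseline, sd, 30,
                     kernel_sigma=0.0, baseline_window=(-0.5, 0.0))


class TestDetectResponse:
    def test_flat_curve_not_significant(self):
        call = detect_response(_curve_with_bump(0.0, 0.1, 0.1))
        assert not call.significant and call.sign == "none"

    def test_five_sd_bump_called_excitatory_with_onset(self):
        call = detect_response(_curve_with_bump(5.0, 0.150, 0.100))
        assert call.significant and call.sign == "excitatory"
        assert call.onset_latency == pytest.approx(0.150, abs=0.002)

    def test_negative_bump_called_inhibitory(self):
        call = detect_response(_curve_with_bump(-5.0, 0.2, 0.1))
        assert call.significant and call.sign == "inhibitory"

    def test_both_direction_runs_called_dual(self):
        t = np.arange(-0.5, 0.5, 0.001)
        rate = np.full(t.size, 10.0)
        rate[(t >= 0.1) & (t < 0.2)] += 5 * 1.5
        rate[(t >= 0.3) & (t < 0.4)] -= 5 * 1.5
        curve = RateCurve(t, rate, rate[None, :], 10.0, 1.5, 30, 0.0, (-0.5, 0.0))
        assert detect_response(curve).sign == "dual"

    def test_brief_excursion_fails_persistence(self):
        call = detect_response(_curve_with_bump(5.0, 0.2, 0.010))
        assert not call.significant

    def test_bump_outside_window_ignored(self):
        call = detect_response(_curve_with_bump(5.0, -0.3, 0.1))
        assert not call.significant

    def test_degenerate_baseline_flagged_not_crashing(self):
        t = np.arange(-0.5, 0.5, 0.001)
        curve = RateCurve(t, np.zeros(t.size), np.zeros((1, t.size)), 0.0, 0.0, 5)
        call = detect_response(curve)
        assert not call.significant and call.degenerate

    def test_detection_monotone_in_amplitude(self, rng):
        """P(detect) non-decreasing over bump amplitudes at fixed duration."""
        amps = [1, 2, 3, 5, 8]
        det = []
        for amp in amps:
            hits = 0
            for rep in range(40):
                sub = np.random.default_rng(600 + rep)
                onsets = 10.0 + 20.0 * np.arange(20)
                times = []
                for o in onsets:
                    n = sub.poisson(10 * 1.2)
                    tt = sub.uniform(o - 0.6, o + 0.6, n)
                    nb = sub.poisson(amp * 2.5 * 0.1)  # bump spikes over 100 ms
                    tb = sub.uniform(o + 0.15, o + 0.25, nb)
                    times.append(np.concatenate([tt, tb]))
                spikes = np.unique(np.concatenate(times))
                curve = spike_density(SpikeTrain("u", spikes), EventSeries(onsets))
                hits += detect_response(curve).significant
            det.append(hits / 40)
        assert all(b >= a - 0.075 for a, b in zip(det, det[1:]))
        assert det[-1] > det[0]


class TestClassification:
    E = ResponseCall(True, "excitatory", 0.10)
    I = ResponseCall(True, "inhibitory", 0.12)
    D = ResponseCall(True, "dual", 0.20)
    N = ResponseCall(False, "none", None)

    @pytest.mark.parametrize(
        "sleep,wake,expected",
        [
            (E, N, "sleep_only"),
            (N, E, "wake_only"),
            (E, I, "both_opposite"),
            (E, D, "both_opposite"),   # dual differs from a pure sign
            (E, E, "both_same"),
            (D, D, "both_same"),
            (N, N, "none"),
        ],
    )
    def test_category_matrix(self, sleep, wake, expected):
        assert classify_cell(sleep, wake).category == expected

    def test_latency_difference_rule(self):
        near = classify_cell(
            ResponseCall(True, "excitatory", 0.10), ResponseCall(True, "excitatory", 0.12)
        )
        far = classify_cell(
            ResponseCall(True, "excitatory", 0.10), ResponseCall(True, "excitatory", 0.18)
        )
        assert near.category == "both_same" and not near.latency_differs
        assert far.latency_differs

    def test_tabulation_partition(self):
        cats = (
            [CellCategory("sleep_only", False)] * 24
            + [CellCategory("wake_only", False)] * 4
            + [CellCategory("both_opposite", True)] * 6
            + [CellCategory("both_same", False)] * 1
            + [CellCategory("none", False)] * 32
        )
        tab = tabulate_cells({"cat1": cats})
        col = tab["cat1"]
        assert col["recorded"] == 67 and col["responded"] == 35
        assert col["responded"] + col["none"] == col["recorded"]
        assert (
            col["sleep_only"] + col["wake_only"] + col["both_opposite"] + col["both_same"]
            == col["responded"]
        )

    def test_empty_population_all_zero(self):
        tab = tabulate_cells({"g": []})
        assert tab["g"].sum() == 0
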