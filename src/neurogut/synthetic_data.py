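"""Seed-controlled generators for synthetic recordings with known structure.

Every analysis stage in this package is validated against data produced
here: EEG whose delta/spindle power rises and gamma power falls in SWS, LFP
trials carrying a state-dependent evoked waveform in 1/f-like noise,
inhomogeneous-Poisson spike trains with stimulus-locked excitation or
suppression per state, and duodenal signals combining a sub-2 Hz slow-wave
carrier with irregular 3-10 Hz burst packets and optional stimulus-locked
amplitude modulation.

All generators are pure functions of (parameters, seed): identical inputs
give bit-identical outputs.  Study-condition defaults follow the recording
protocol the analyses assume: 45-60 s uniform interstimulus intervals, a
0.3 Hz slow-wave carrier with burst packets at 4-5 per minute, and evoked
response latencies at or after the 40 ms artifact-blanked interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_signals import (
    ContinuousRecording,
    EventSeries,
    SpikeTrain,
    StateHypnogram,
    STATES,
    SWS,
    WAKE,
)
from .vigilance import BandSet

RESPONSE_SIGNS = ("excitatory", "inhibitory", "dual")


@dataclass
class EvokedSpec:
    """One stimulus-locked response expressed in one vigilance state.

    ``amplitude`` is the kernel peak: in baseline-noise-SD units for LFP
    generation; for spike generation it is the peak additive rate in Hz
    (excitatory), or the peak fractional suppression in [0, 1] (inhibitory).
    """

    latency_s: float = 0.1
    amplitude: float = 5.0
    duration_s: float = 0.2
    sign: str = "excitatory"
    state: str = SWS

    def __post_init__(self) -> None:
        if self.latency_s < 0.04:
            raise ValueError("latency must be >= 0.04 s (post-blanking)")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.sign not in RESPONSE_SIGNS:
            raise ValueError(f"sign must be one of {RESPONSE_SIGNS}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")


@dataclass
class GutSpec:
    """Parameters of the synthetic duodenal myoelectric signal."""

    slow_wave_hz: float = 0.3
    burst_rate_per_min: float = 4.5
    burst_band_hz: tuple[float, float] = (3.0, 10.0)
    stim_gain: float = 1.0          # slow-wave amplitude multiplier post-stimulus
    stim_effect_s: float = 40.0
    burst_stim_gain: float = 1.0    # burst-probability multiplier post-stimulus
    stim_state: str | None = SWS    # None: stimulus effect in every state
    burst_amp: float = 0.5          # burst packet amplitude rel. slow-wave
    burst_len_s: float = 1.5
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not self.slow_wave_hz < 2:
            raise ValueError("slow-wave fundamental must be below 2 Hz")
        if self.burst_band_hz[0] <= 2:
            raise ValueError("burst band must lie above 2 Hz")


def alpha_kernel(t: np.ndarray, latency: float, duration: float) -> np.ndarray:
    """Unit-peak causal alpha function: peaks at ``latency + duration/5``."""
    tau = duration / 5.0
    tt = (t - latency) / tau
    out = np.where(tt > 0, tt * np.exp(1.0 - tt), 0.0)
    return out


def biphasic_kernel(t: np.ndarray, latency: float, duration: float) -> np.ndarray:
    """Positive alpha lobe followed by a negative one (dual responses)."""
    return alpha_kernel(t, latency, duration) - alpha_kernel(t, latency + duration, duration)


def gen_hypnogram(segment_durations: list[tuple[str, float]]) -> StateHypnogram:
    """Contiguous hypnogram starting at 0, intervals in the order given."""
    intervals = []
    t = 0.0
    for state, dur in segment_durations:
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        intervals.append((t, t + dur, state))
        t += dur
    return StateHypnogram(intervals)


def gen_stim_times(
    hypnogram: StateHypnogram,
    isi: tuple[float, float] = (45.0, 60.0),
    seed: int | np.random.Generator = 0,
    label: str = "stim",
) -> EventSeries:
    """Stimulus train with i.i.d. uniform ISIs confined to the hypnogram span."""
    lo, hi = isi
    if not (0 < lo <= hi):
        raise ValueError("need 0 < min_isi <= max_isi")
    rng = np.random.default_rng(seed)
    start, end = hypnogram.span
    if end - start < lo:
        warnings.warn("hypnogram span shorter than minimum ISI; no events")
        return EventSeries(np.array([]), label=label)
    onsets = []
    t = start
    while True:
        t += rng.uniform(lo, hi)
        if t >= end:
            break
        onsets.append(t)
    return EventSeries(np.asarray(onsets), label=label)


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian noise normalised to unit variance."""
    white = rng.standard_normal(n)
    lo, hi = band
    if hi > rate / 2:
        raise ValueError(f"band edge {hi} Hz above Nyquist {rate / 2} Hz")
    if lo <= 0:
        sos = signal.butter(4, hi, btype="lowpass", fs=rate, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_series(hypnogram: StateHypnogram, t: np.ndarray) -> np.ndarray:
    """State per sample: 0 = WAKE, 1 = SWS, -1 = unstaged."""
    out = np.full(t.size, -1, dtype=int)
    for start, end, state in hypnogram.intervals:
        out[(t >= start) & (t < end)] = 1 if state == SWS else 0
    return out


def gen_eeg(
    hypnogram: StateHypnogram,
    band_gains: dict[str, dict[str, float]] | None = None,
    rate: float = 200.0,
    seed: int | np.random.Generator = 0,
    bands: BandSet | None = None,
) -> ContinuousRecording:
    """EEG-like signal: per-band unit-variance noise scaled per-state.

    ``band_gains`` maps state -> band name -> amplitude gain (power scales
    with gain squared); gains switch instantaneously at hypnogram
    boundaries.  Defaults express the canonical vigilance signature: delta
    and spindle amplitude doubled in SWS, gamma halved.
    """
    if rate < 200:
        raise ValueError("EEG rate must be >= 200 Hz (75 Hz gamma edge)")
    bands = bands or BandSet()
    if band_gains is None:
        band_gains = {
            WAKE: {"delta": 1.0, "spindles": 1.0, "gamma": 1.0},
            SWS: {"delta": 2.0, "spindles": 2.0, "gamma": 0.5},
        }
    for gains in band_gains.values():
        if any(g < 0 for g in gains.values()):
            raise ValueError("gains must be non-negative")
    rng = np.random.default_rng(seed)
    start, end = hypnogram.span
    n = int(round((end - start) * rate))
    t = start + np.arange(n) / rate
    state = _state_series(hypnogram, t)
    sig = np.zeros(n)
    for name, band in bands.items():
        noise = _band_noise(rng, n, rate, band)
        gain = np.ones(n)
        gain[state == 0] = band_gains[WAKE].get(name, 1.0)
        gain[state == 1] = band_gains[SWS].get(name, 1.0)
        sig += gain * noise
    return ContinuousRecording(sig, rate, start_time=start, channel="EEG", label="synthetic")


def colored_noise(
    rng: np.random.Generator, n: int, rate: float, beta: float = 1.0, sd: float = 1.0
) -> np.ndarray:
    """Gaussian 1/f^beta noise with the requested standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-beta / 2.0)
    x = np.fft.irfft(spec, n=n)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def gen_lfp_evoked(
    hypnogram: StateHypnogram,
    events: EventSeries,
    specs: list[EvokedSpec],
    noise_model: tuple[float, float] = (1.0, 1.0),
    rate: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> ContinuousRecording:
    """LFP: 1/f^beta background plus state-gated stereotyped evoked responses.

    For each event occurring in a spec's state a kernel (alpha function for
    excitatory, its negative for inhibitory, biphasic for dual) is added at
    the spec's latency, scaled to ``amplitude`` noise-SDs at its peak.
    """
    beta, noise_sd = noise_model
    rng = np.random.default_rng(seed)
    start, end = hypnogram.span
    n = int(round((end - start) * rate))
    sig = colored_noise(rng, n, rate, beta, noise_sd)
    t_support = np.arange(0, 1 + max((s.latency_s + 3 * s.duration_s for s in specs), default=0),
                          1.0 / rate)
    for spec in specs:
        if spec.sign == "dual":
            kern = biphasic_kernel(t_support, spec.latency_s, spec.duration_s)
        else:
            kern = alpha_kernel(t_support, spec.latency_s, spec.duration_s)
            if spec.sign == "inhibitory":
                kern = -kern
        kern = kern * spec.amplitude * noise_sd
        for onset in events.onsets:
            if hypnogram.state_at(onset) != spec.state:
                continue
            k0 = int(round((onset - start) * rate))
            k1 = min(k0 + kern.size, n)
            if k0 < n:
                sig[k0:k1] += kern[: k1 - k0]
    return ContinuousRecording(sig, rate, start_time=start, channel="LFP", label="synthetic")


def gen_spikes(
    hypnogram: StateHypnogram,
    events: EventSeries,
    baseline_hz: dict[str, float] | float = 10.0,
    specs: list[EvokedSpec] | None = None,
    seed: int | np.random.Generator = 0,
    unit_id: str = "u0",
    grid_dt: float = 0.001,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train via thinning.

    Rate = state baseline plus event-locked modulation per spec: excitatory
    specs add an alpha-kernel bump of ``amplitude`` Hz; inhibitory specs
    multiply the rate by ``(1 - amplitude * kernel)``, clipped at zero; dual
    specs apply an excitatory lobe then an inhibitory one.
    """
    specs = specs or []
    rng = np.random.default_rng(seed)
    start, end = hypnogram.span
    n = int(round((end - start) / grid_dt))
    t = start + np.arange(n) * grid_dt
    if isinstance(baseline_hz, dict):
        if any(v <= 0 for v in baseline_hz.values()):
            raise ValueError("baseline rates must be positive")
        state = _state_series(hypnogram, t)
        rate = np.where(state == 1, baseline_hz.get(SWS, 1.0), baseline_hz.get(WAKE, 1.0))
        rate = rate.astype(float)
    else:
        if baseline_hz <= 0:
            raise ValueError("baseline rate must be positive")
        rate = np.full(n, float(baseline_hz))

    for spec in specs:
        supp = np.arange(0, spec.latency_s + 3 * spec.duration_s, grid_dt)
        add = np.zeros_like(supp)
        mult = np.ones_like(supp)
        if spec.sign in ("excitatory", "dual"):
            add = spec.amplitude * alpha_kernel(supp, spec.latency_s, spec.duration_s)
        if spec.sign == "inhibitory":
            depth = min(max(spec.amplitude, 0.0), 1.0)
            mult = 1.0 - depth * alpha_kernel(supp, spec.latency_s, spec.duration_s)
        if spec.sign == "dual":
            mult = 1.0 - alpha_kernel(supp, spec.latency_s + spec.duration_s, spec.duration_s)
        for onset in events.onsets:
            if hypnogram.state_at(onset) != spec.state:
                continue
            k0 = int(round((onset - start) / grid_dt))
            k1 = min(k0 + supp.size, n)
            if k0 >= n:
                continue
            rate[k0:k1] = rate[k0:k1] * mult[: k1 - k0] + add[: k1 - k0]

    if np.any(rate < 0):
        warnings.warn("modulation drove rate negative; clipped at 0")
        rate = np.clip(rate, 0.0, None)
    lam_max = rate.max()
    if lam_max <= 0:
        return SpikeTrain(unit_id, np.array([]))
    span = end - start
    n_cand = rng.poisson(lam_max * span)
    cand = np.sort(rng.uniform(start, end, n_cand))
    idx = np.minimum(((cand - start) / grid_dt).astype(int), n - 1)
    accept = rng.uniform(0, 1, n_cand) < rate[idx] / lam_max
    times = np.unique(cand[accept])
    return SpikeTrain(unit_id, times)


def gen_gut(
    hypnogram: StateHypnogram,
    events: EventSeries,
    spec: GutSpec | None = None,
    rate: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> ContinuousRecording:
    """Duodenal myoelectric signal: slow-wave carrier plus gated burst packets.

    The slow-wave carrier at ``slow_wave_hz`` has a slowly varying random
    amplitude; 3-10 Hz burst packets are placed on randomly selected
    slow-wave crests at ``burst_rate_per_min``.  When ``stim_gain != 1`` the
    slow-wave amplitude is multiplied by it for ``stim_effect_s`` after each
    stimulus delivered in ``stim_state``; ``burst_stim_gain`` likewise scales
    the per-crest burst probability post-stimulus.
    """
    spec = spec or GutSpec()
    if rate < 50:
        raise ValueError("gut sampling rate must be >= 50 Hz")
    rng = np.random.default_rng(seed)
    start, end = hypnogram.span
    n = int(round((end - start) * rate))
    t = start + np.arange(n) / rate

    # slowly varying positive amplitude: random knots every 15 s, interpolated
    knot_t = np.arange(start, end + 15.0, 15.0)
    knots = 1.0 + 0.3 * rng.standard_normal(knot_t.size)
    ampl = np.clip(np.interp(t, knot_t, knots), 0.2, None)

    # stimulus-locked gain windows
    gain = np.ones(n)
    burst_gain = np.ones(n)
    for onset in events.onsets:
        if spec.stim_state is not None and hypnogram.state_at(onset) != spec.stim_state:
            continue
        m = (t >= onset + 0.5) & (t < onset + 0.5 + spec.stim_effect_s)
        gain[m] *= spec.stim_gain
        burst_gain[m] *= spec.burst_stim_gain

    phase = rng.uniform(0, 2 * np.pi)
    carrier = ampl * gain * np.sin(2 * np.pi * spec.slow_wave_hz * (t - start) + phase)

    # burst packets gated to slow-wave crests
    burst_env = np.zeros(n)
    if spec.burst_rate_per_min > 0:
        crest_phase = (np.pi / 2 - phase) % (2 * np.pi)
        period = 1.0 / spec.slow_wave_hz
        crest_times = start + crest_phase / (2 * np.pi * spec.slow_wave_hz) + \
            period * np.arange(int((end - start) / period) + 1)
        crest_times = crest_times[crest_times < end]
        p_base = spec.burst_rate_per_min / (60.0 * spec.slow_wave_hz)
        w = int(round(spec.burst_len_s * rate))
        win = signal.windows.hann(w)
        for ct in crest_times:
            k = int(round((ct - start) * rate))
            p = min(1.0, p_base * burst_gain[min(k, n - 1)])
            if rng.uniform() >= p:
                continue
            k0 = max(0, k - w // 2)
            k1 = min(n, k0 + w)
            local_amp = ampl[min(k, n - 1)] * gain[min(k, n - 1)]
            burst_env[k0:k1] += spec.burst_amp * local_amp * win[: k1 - k0]
    burst_carrier = _band_noise(rng, n, rate, spec.burst_band_hz) if spec.burst_rate_per_min > 0 \
        else np.zeros(n)

    sig = carrier + burst_env * burst_carrier + spec.noise_sd * rng.standard_normal(n)
    return ContinuousRecording(sig, rate, start_time=start, channel="GUT", label="synthetic")
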