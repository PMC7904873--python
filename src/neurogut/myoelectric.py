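"""Stimulus-locked analysis of duodenal myoelectric activity.

Duodenal myoelectric signals combine sub-2 Hz pacemaker slow waves ("simple
waves", electrical control activity) with irregular 3-10 Hz spike-potential
bursts riding on some slow-wave crests.  Two stimulus-locked tests are run
per session:

* **Simple waves** — multitaper 0-2 Hz band power in the 40 s before each
  stimulus vs the 40 s starting 0.5 s after it, paired signed-rank across
  events.
* **Spike potentials** — 3-10 Hz band power in a 20 s window centred at the
  post-stimulus extremum of the simple-wave amplitude modulation vs the
  time-mirrored 20 s window before the stimulus.

The modulation extremum is located on the amplitude envelope of the 0-2 Hz
filtered post-stimulus trace (Hilbert magnitude, 5 s moving-average smooth);
sessions whose simple-wave power decreases use the envelope minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import hilbert

from .core_signals import (
    ContinuousRecording,
    EventSeries,
    InsufficientDataError,
    StateHypnogram,
    bandpass,
)
from .vigilance import band_power, multitaper_psd


@dataclass
class MyoWindows:
    """Analysis configuration for gut myoelectric responses."""

    simple_band: tuple[float, float] = (0.0, 2.0)
    burst_band: tuple[float, float] = (3.0, 10.0)
    pre_post_s: float = 40.0        # simple-wave comparison window length
    post_offset_s: float = 0.5      # post window starts this long after onset
    burst_window_s: float = 20.0    # spike-potential window length
    envelope_smooth_s: float = 5.0
    nw: float = 3.0
    n_tapers: int = 5
    alpha: float = 0.05


@dataclass
class BandTestResult:
    p_value: float
    direction: str                  # increase / decrease / none
    pre_power: np.ndarray
    post_power: np.ndarray
    n_events: int
    n_dropped: int


@dataclass
class ExtremumResult:
    time: float                     # seconds relative to onset
    degenerate: bool = False


@dataclass
class MyoSessionResult:
    n_events: int
    simple: BandTestResult
    burst: BandTestResult | None
    extremum_times: list[float] = field(default_factory=list)


def _slice(rec: ContinuousRecording, t0: float, t1: float) -> np.ndarray | None:
    """Samples in [t0, t1), or None when outside the recording."""
    k0 = int(round((t0 - rec.start_time) * rec.rate))
    k1 = k0 + int(round((t1 - t0) * rec.rate))
    if k0 < 0 or k1 > rec.n_samples:
        return None
    return rec.samples[k0:k1]


def _usable_events(
    events: EventSeries,
    hypnogram: StateHypnogram | None,
    state: str | None,
    span: tuple[float, float],
) -> np.ndarray:
    """Onsets that are artifact-free and (optionally) confined to one state."""
    keep = []
    for onset, bad in zip(events.onsets, events.artifact_flag):
        if bad:
            continue
        if hypnogram is not None:
            i0 = hypnogram.interval_index(onset + span[0])
            i1 = hypnogram.interval_index(onset + span[1])
            if i0 is None or i0 != i1:
                continue
            if state is not None and hypnogram.intervals[i0][2] != state:
                continue
        keep.append(onset)
    return np.asarray(keep)


def _paired_band_test(
    pre: list[float], post: list[float], alpha: float
) -> tuple[float, str]:
    pre_a, post_a = np.asarray(pre), np.asarray(post)
    diff = post_a - pre_a
    if np.all(diff == 0):
        return 1.0, "none"
    _, p = stats.wilcoxon(pre_a, post_a)
    if p < alpha:
        return float(p), "increase" if np.median(diff) > 0 else "decrease"
    return float(p), "none"


def simple_wave_response(
    rec: ContinuousRecording,
    events: EventSeries,
    cfg: MyoWindows | None = None,
    hypnogram: StateHypnogram | None = None,
    state: str | None = None,
) -> BandTestResult:
    """Paired pre/post comparison of 0-2 Hz simple-wave band power."""
    cfg = cfg or MyoWindows()
    T, off = cfg.pre_post_s, cfg.post_offset_s
    onsets = _usable_events(events, hypnogram, state, (-T, off + T))
    pre_p, post_p = [], []
    dropped = 0
    for onset in onsets:
        pre = _slice(rec, onset - T, onset)
        post = _slice(rec, onset + off, onset + off + T)
        if pre is None or post is None:
            dropped += 1
            continue
        psd_pre = multitaper_psd(
            ContinuousRecording(pre, rec.rate), cfg.nw, cfg.n_tapers
        )
        psd_post = multitaper_psd(
            ContinuousRecording(post, rec.rate), cfg.nw, cfg.n_tapers
        )
        pre_p.append(band_power(psd_pre, cfg.simple_band))
        post_p.append(band_power(psd_post, cfg.simple_band))
    if len(pre_p) < 6:
        raise InsufficientDataError(
            f"simple-wave test needs >= 6 usable events, got {len(pre_p)}"
        )
    p, direction = _paired_band_test(pre_p, post_p, cfg.alpha)
    return BandTestResult(
        p, direction, np.asarray(pre_p), np.asarray(post_p), len(pre_p), dropped
    )


def modulation_extremum(
    rec: ContinuousRecording,
    event_onset: float,
    cfg: MyoWindows | None = None,
    direction: str = "increase",
) -> ExtremumResult:
    """Time (relative to onset) of the post-stimulus simple-wave envelope extremum.

    The post window is band-limited to the simple-wave band, its analytic-
    signal magnitude smoothed with a moving average, and the time of the
    maximum (minimum for ``direction="decrease"``) returned.
    """
    cfg = cfg or MyoWindows()
    T, off = cfg.pre_post_s, cfg.post_offset_s
    post = _slice(rec, event_onset + off, event_onset + off + T)
    if post is None:
        raise ValueError("post-stimulus window truncated by the recording")
    seg = ContinuousRecording(post, rec.rate)
    lo, hi = cfg.simple_band
    filtered = bandpass(seg, lo, hi).samples
    env = np.abs(hilbert(filtered))
    w = max(1, int(round(cfg.envelope_smooth_s * rec.rate)))
    kernel = np.ones(w) / w
    env = np.convolve(env, kernel, mode="same")
    if np.max(env) <= 1e-12:
        return ExtremumResult(time=off + T / 2.0, degenerate=True)
    idx = int(np.argmax(env)) if direction != "decrease" else int(np.argmin(env))
    return ExtremumResult(time=off + idx / rec.rate)


def spike_potential_response(
    rec: ContinuousRecording,
    events: EventSeries,
    extrema: list[float],
    cfg: MyoWindows | None = None,
) -> BandTestResult:
    """Paired 3-10 Hz power: post window centred at the extremum vs its mirror.

    For an extremum at +T the post window is ``[T-10, T+10)`` after onset and
    the pre window the time-mirrored ``[-T-10, -T+10)``.  T is clamped so
    neither window crosses the stimulus instant; events whose mirrored pre
    window leaves the recording are dropped and counted.
    """
    cfg = cfg or MyoWindows()
    half = cfg.burst_window_s / 2.0
    t_min = half + cfg.post_offset_s
    pre_p, post_p = [], []
    dropped = 0
    for onset, T in zip(events.onsets, extrema):
        T = max(float(T), t_min)  # clamp: window must clear the stimulus
        post = _slice(rec, onset + T - half, onset + T + half)
        pre = _slice(rec, onset - T - half, onset - T + half)
        if pre is None or post is None:
            dropped += 1
            continue
        psd_pre = multitaper_psd(
            ContinuousRecording(pre, rec.rate), cfg.nw, cfg.n_tapers
        )
        psd_post = multitaper_psd(
            ContinuousRecording(post, rec.rate), cfg.nw, cfg.n_tapers
        )
        pre_p.append(band_power(psd_pre, cfg.burst_band))
        post_p.append(band_power(psd_post, cfg.burst_band))
    if len(pre_p) < 6:
        raise InsufficientDataError(
            f"spike-potential test needs >= 6 usable events, got {len(pre_p)}"
        )
    p, direction = _paired_band_test(pre_p, post_p, cfg.alpha)
    return BandTestResult(
        p, direction, np.asarray(pre_p), np.asarray(post_p), len(pre_p), dropped
    )


def analyze_session(
    rec: ContinuousRecording,
    events: EventSeries,
    cfg: MyoWindows | None = None,
    hypnogram: StateHypnogram | None = None,
    state: str | None = None,
) -> MyoSessionResult:
    """Full per-session gut analysis: simple waves, extrema, spike potentials."""
    cfg = cfg or MyoWindows()
    simple = simple_wave_response(rec, events, cfg, hypnogram, state)
    ext_dir = "decrease" if simple.direction == "decrease" else "increase"
    onsets = _usable_events(
        events, hypnogram, state, (-cfg.pre_post_s, cfg.post_offset_s + cfg.pre_post_s)
    )
    extrema = []
    for onset in onsets:
        try:
            extrema.append(modulation_extremum(rec, onset, cfg, ext_dir).time)
        except ValueError:
            extrema.append(np.nan)
    usable = ~np.isnan(extrema)
    burst = None
    try:
        burst = spike_potential_response(
            rec,
            EventSeries(onsets[usable]),
            [e for e, u in zip(extrema, usable) if u],
            cfg,
        )
    except InsufficientDataError:
        burst = None
    return MyoSessionResult(
        n_events=len(onsets), simple=simple, burst=burst, extremum_times=list(extrema)
    )
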