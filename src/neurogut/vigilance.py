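"""Multitaper band power, sleep/wake staging validation, disturbance test.

Power spectral densities are estimated with Slepian (DPSS) multitapers,
time-bandwidth product NW = 3 and K = 5 tapers by default, as the
eigenvalue-weighted average of the tapered periodograms.  The one-sided
density is normalised so that its integral over [0, Nyquist] approximates
the signal variance.

Two analyses are built on the band powers:

* ``compare_states`` — tiles the hypnogram with fixed-length windows and
  rank-sum-tests SWS vs WAKE band power per band (staging validation: delta
  and spindle power should be higher in SWS, gamma higher in WAKE).
* ``disturbance_test`` — paired signed-rank comparison of band power in the
  10 s before vs after each stimulus.  An "awakening" signature is a
  significant delta or spindle decrease or gamma increase after stimuli
  delivered in sleep; the opposite pattern is flagged as a (mild) somnogenic
  hint.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.signal import windows


from .core_signals import (
    ContinuousRecording,
    EventSeries,
    InsufficientDataError,
    StateHypnogram,
    SWS,
    WAKE,
)


@lru_cache(maxsize=64)
def _dpss_cached(n: int, nw: float, k: int):
    """Slepian tapers are expensive for long segments; treat as read-only."""
    return windows.dpss(n, nw, k, return_ratios=True)


@dataclass
class BandSet:
    """Vigilance-sensitive EEG bands (Hz)."""

    delta: tuple[float, float] = (1.0, 4.0)
    spindles: tuple[float, float] = (7.0, 14.0)
    gamma: tuple[float, float] = (30.0, 75.0)

    def items(self):
        return [("delta", self.delta), ("spindles", self.spindles), ("gamma", self.gamma)]


@dataclass
class PsdEstimate:
    frequencies: np.ndarray
    power: np.ndarray
    n_tapers: int
    nw: float
    segment_length: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power density must be non-negative")


@dataclass
class BandComparison:
    band: str
    p_value: float
    direction: str            # "sws_higher" / "wake_higher" / "none"
    n_sws: int
    n_wake: int
    statistic: float


@dataclass
class DisturbanceVerdict:
    band_p: dict[str, float]
    band_direction: dict[str, str]     # "increase" / "decrease" / "none"
    awakening: bool
    somnogenic_hint: bool
    awakening_bonferroni: bool
    n_events: int
    n_dropped: int


def multitaper_psd(
    segment: ContinuousRecording, nw: float = 3.0, n_tapers: int = 5
) -> PsdEstimate:
    """Eigenvalue-weighted multitaper PSD of one segment (mean removed)."""
    if n_tapers > 2 * nw - 1:
        raise ValueError(f"n_tapers must be <= 2*NW-1 = {2 * nw - 1}")
    n = segment.n_samples
    if n < segment.rate:
        raise InsufficientDataError("segment must be at least 1 s long")
    x = segment.samples - segment.samples.mean()
    tapers, eigvals = _dpss_cached(n, float(nw), int(n_tapers))
    # tapers have unit energy; |FFT|^2 / fs is a density per taper
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / segment.rate
    psd = np.average(spectra, axis=0, weights=eigvals)
    # one-sided: double everything except DC (and Nyquist when n is even)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / segment.rate)
    return PsdEstimate(freqs, psd, n_tapers, nw, n / segment.rate)


def band_power(psd: PsdEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the density over ``band`` (endpoints interpolated)."""
    lo, hi = band
    f, p = psd.frequencies, psd.power
    if hi <= f[0] or lo >= f[-1]:
        raise ValueError(f"band ({lo}, {hi}) does not overlap the frequency grid")
    lo, hi = max(lo, f[0]), min(hi, f[-1])
    inner = (f > lo) & (f < hi)
    fs = np.concatenate([[lo], f[inner], [hi]])
    ps = np.concatenate([[np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]])
    return float(np.trapezoid(ps, fs))


def _tile_band_powers(
    rec: ContinuousRecording,
    hypnogram: StateHypnogram,
    bands: BandSet,
    window_s: float,
    nw: float,
    n_tapers: int,
) -> dict[str, dict[str, list[float]]]:
    """Non-overlapping window band powers per state: {band: {state: [power]}}."""
    out: dict[str, dict[str, list[float]]] = {
        name: {WAKE: [], SWS: []} for name, _ in bands.items()
    }
    n_win = int(round(window_s * rec.rate))
    for start, end, state in hypnogram.intervals:
        t = start
        while t + window_s <= end + 1e-9:
            k0 = int(round((t - rec.start_time) * rec.rate))
            if k0 < 0 or k0 + n_win > rec.n_samples:
                break
            seg = ContinuousRecording(
                rec.samples[k0 : k0 + n_win], rec.rate, t, rec.channel
            )
            psd = multitaper_psd(seg, nw, n_tapers)
            for name, band in bands.items():
                out[name][state].append(band_power(psd, band))
            t += window_s
    return out


def compare_states(
    rec: ContinuousRecording,
    hypnogram: StateHypnogram,
    bands: BandSet | None = None,
    window_s: float = 10.0,
    nw: float = 3.0,
    n_tapers: int = 5,
    alpha: float = 0.05,
) -> dict[str, BandComparison]:
    """Rank-sum SWS vs WAKE band power over hypnogram-tiled windows."""
    bands = bands or BandSet()
    powers = _tile_band_powers(rec, hypnogram, bands, window_s, nw, n_tapers)
    first = next(iter(powers.values()))
    for state in (WAKE, SWS):
        if len(first[state]) < 3:
            raise InsufficientDataError(
                f"fewer than 3 analysis windows in state {state}"
            )
    results = {}
    for name, _ in bands.items():
        sws = np.asarray(powers[name][SWS])
        wake = np.asarray(powers[name][WAKE])
        stat, p = stats.ranksums(sws, wake)
        direction = "none"
        if p < alpha:
            direction = "sws_higher" if np.median(sws) > np.median(wake) else "wake_higher"
        results[name] = BandComparison(name, float(p), direction, sws.size, wake.size, float(stat))
    return results


def disturbance_test(
    rec: ContinuousRecording,
    events: EventSeries,
    hypnogram: StateHypnogram,
    bands: BandSet | None = None,
    pre_post_s: float = 10.0,
    nw: float = 3.0,
    n_tapers: int = 5,
    alpha: float = 0.05,
) -> DisturbanceVerdict:
    """Pre vs post stimulus band-power comparison (paired signed-rank).

    Pre window is ``[onset - T, onset)``, post window ``(onset, onset + T]``
    (the stimulus sample itself excluded).  Events whose combined span
    crosses a hypnogram interval boundary are dropped and counted.  Caller
    passes events restricted to the state of interest (SWS for the
    sleep-quality question).
    """
    bands = bands or BandSet()
    n_win = int(round(pre_post_s * rec.rate))
    pre_p: dict[str, list[float]] = {name: [] for name, _ in bands.items()}
    post_p: dict[str, list[float]] = {name: [] for name, _ in bands.items()}
    dropped = 0
    for onset in events.onsets:
        i0 = hypnogram.interval_index(onset - pre_post_s)
        i1 = hypnogram.interval_index(onset + pre_post_s)
        if i0 is None or i0 != i1:
            dropped += 1
            continue
        k_on = int(round((onset - rec.start_time) * rec.rate))
        if k_on - n_win < 0 or k_on + 1 + n_win > rec.n_samples:
            dropped += 1
            continue
        pre_seg = ContinuousRecording(rec.samples[k_on - n_win : k_on], rec.rate)
        post_seg = ContinuousRecording(rec.samples[k_on + 1 : k_on + 1 + n_win], rec.rate)
        psd_pre = multitaper_psd(pre_seg, nw, n_tapers)
        psd_post = multitaper_psd(post_seg, nw, n_tapers)
        for name, band in bands.items():
            pre_p[name].append(band_power(psd_pre, band))
            post_p[name].append(band_power(psd_post, band))

    n_used = len(next(iter(pre_p.values())))
    if n_used < 6:
        raise InsufficientDataError(
            f"disturbance test needs >= 6 usable events, got {n_used}"
        )

    band_pv: dict[str, float] = {}
    band_dir: dict[str, str] = {}
    for name, _ in bands.items():
        pre_arr = np.asarray(pre_p[name])
        post_arr = np.asarray(post_p[name])
        diff = post_arr - pre_arr
        if np.all(diff == 0):
            band_pv[name], band_dir[name] = 1.0, "none"
            continue
        _, p = stats.wilcoxon(pre_arr, post_arr)
        band_pv[name] = float(p)
        if p < alpha:
            band_dir[name] = "increase" if np.median(diff) > 0 else "decrease"
        else:
            band_dir[name] = "none"

    def _awake(sig: dict[str, str]) -> bool:
        return (
            sig.get("delta") == "decrease"
            or sig.get("spindles") == "decrease"
            or sig.get("gamma") == "increase"
        )

    n_bands = len(band_pv)
    dir_bonf = {
        name: (band_dir[name] if band_pv[name] < alpha / n_bands else "none")
        for name in band_pv
    }
    somnogenic = (
        band_dir.get("delta") == "increase"
        or band_dir.get("spindles") == "increase"
        or band_dir.get("gamma") == "decrease"
    )
    return DisturbanceVerdict(
        band_p=band_pv,
        band_direction=band_dir,
        awakening=_awake(band_dir),
        somnogenic_hint=somnogenic,
        awakening_bonferroni=_awake(dir_bonf),
        n_events=n_used,
        n_dropped=dropped,
    )
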