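"""Peristimulus spike-density estimation, response detection, classification.

Spike times are convolved with a unit-area Gaussian kernel (SD 20 ms,
truncated at +/-4 sigma and renormalised) on a 1 ms grid to form per-trial
firing-rate curves; the trial average is the peristimulus density.  A unit is
called responsive in a state when the averaged curve leaves a +/-3 SD band
around its pre-stimulus baseline and stays at least 2 SD away for a
contiguous 30 ms run inside the 40-500 ms post-stimulus window.  Response
sign (excitatory / inhibitory / dual) and onset latency follow from the
qualifying runs.  Sleep and wake calls per unit are combined into the
five-way cell classification used for the population contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_signals import EventSeries, InsufficientDataError, SpikeTrain

GRID_DT = 0.001          # 1 ms resample grid for rate curves
KERNEL_SIGMA = 0.020     # Gaussian SD (interpreted as SD, not FWHM)
KERNEL_TRUNC = 4.0       # kernel support +/- 4 sigma, renormalised to unit area
BASELINE_WINDOW = (-0.5, 0.0)
ANALYSIS_WINDOW = (0.040, 0.500)
MIN_RUN_S = 0.030
BASELINE_SD_FLOOR = 0.1  # spikes/s; guards silent baselines


@dataclass
class RateCurve:
    """Peristimulus rate curves with baseline statistics.

    ``baseline_sd`` is the standard deviation of the *trial-averaged* curve
    in the baseline window.  With two or more trials it is estimated from
    the across-trial variance of the single-trial curves (unbiased, high
    degrees of freedom); the naive time-wise SD of the averaged baseline
    segment is biased low because the kernel-smoothed curve is strongly
    autocorrelated over a short window.
    """

    rel_time: np.ndarray
    mean_rate: np.ndarray
    trial_rates: np.ndarray
    baseline_mean: float
    baseline_sd: float
    n_trials: int
    kernel_sigma: float = KERNEL_SIGMA
    baseline_window: tuple[float, float] = BASELINE_WINDOW


@dataclass
class ResponseCall:
    significant: bool
    sign: str                       # excitatory / inhibitory / dual / none
    onset_latency: float | None
    deviation_intervals: list[tuple[float, float]] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class CellCategory:
    category: str                   # sleep_only/wake_only/both_opposite/both_same/none
    latency_differs: bool


CATEGORIES = ("sleep_only", "wake_only", "both_opposite", "both_same", "none")


def spike_density(
    train: SpikeTrain,
    events: EventSeries,
    window: tuple[float, float] = (-0.5, 0.5),
    sigma: float = KERNEL_SIGMA,
) -> RateCurve:
    """Gaussian-kernel peristimulus rate estimate on a 1 ms grid.

    Each spike contributes a unit-area (truncated, renormalised) Gaussian, so
    integrating a trial's curve over the window recovers its spike count for
    spikes whose kernel support lies inside the window.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(events) == 0:
        raise InsufficientDataError("no trials (empty event series)")
    t0, t1 = window
    grid = np.arange(t0, t1, GRID_DT)
    half = KERNEL_TRUNC * sigma
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    # mass inside the +/-4 sigma truncation, used to renormalise to unit area
    from scipy.stats import norm as _norm
    mass = _norm.cdf(KERNEL_TRUNC) - _norm.cdf(-KERNEL_TRUNC)

    rates = np.zeros((len(events), grid.size))
    for i, onset in enumerate(events.onsets):
        rel = train.times - onset
        rel = rel[(rel >= t0 - half) & (rel < t1 + half)]
        for s in rel:
            d = grid - s
            m = np.abs(d) <= half
            rates[i, m] += norm * np.exp(-0.5 * (d[m] / sigma) ** 2) / mass

    mean_rate = rates.mean(axis=0)
    bmask = (grid >= BASELINE_WINDOW[0]) & (grid < BASELINE_WINDOW[1])
    if not bmask.any():
        b_mean, b_sd = 0.0, 0.0
    else:
        b_mean = float(mean_rate[bmask].mean())
        if rates.shape[0] >= 2:
            # SD of the averaged curve via across-trial variance: unbiased,
            # unlike the autocorrelation-deflated time-wise window SD
            v = rates[:, bmask].var(axis=0, ddof=1).mean()
            b_sd = float(np.sqrt(v / rates.shape[0]))
        else:
            b_sd = float(mean_rate[bmask].std(ddof=0))
    return RateCurve(
        rel_time=grid,
        mean_rate=mean_rate,
        trial_rates=rates,
        baseline_mean=b_mean,
        baseline_sd=b_sd,
        n_trials=len(events),
        kernel_sigma=sigma,
        baseline_window=(t0 if t0 > BASELINE_WINDOW[0] else BASELINE_WINDOW[0],
                         BASELINE_WINDOW[1]),
    )


def detect_response(
    curve: RateCurve,
    analysis_window: tuple[float, float] = ANALYSIS_WINDOW,
    sd_floor: float = BASELINE_SD_FLOOR,
) -> ResponseCall:
    """Apply the 3 SD / 2 SD / 30 ms criterion to an averaged rate curve.

    Significant iff some point inside the window deviates from the baseline
    mean by more than 3 SD *and* lies within a contiguous run of >= 30 ms
    where the deviation stays >= 2 SD, the run falling wholly inside the
    window.  Onset latency is the first 3 SD crossing of the earliest
    qualifying run.

    The deviation is taken against the *estimated* baseline mean, so the SD
    unit propagates both uncertainties: for a Gaussian kernel of SD sigma
    the baseline-mean estimate over a window of length T carries an extra
    variance of ``2 * sigma * sqrt(pi) / T`` relative to the curve's own,
    inflating the unit by ``sqrt(1 + 2 sigma sqrt(pi) / T)`` (about 7% at
    the defaults).
    """
    if curve.baseline_sd <= 0:
        return ResponseCall(False, "none", None, degenerate=True)
    t_base = curve.baseline_window[1] - curve.baseline_window[0]
    infl = np.sqrt(1.0 + 2.0 * curve.kernel_sigma * np.sqrt(np.pi) / t_base) \
        if t_base > 0 else 1.0
    sd = max(curve.baseline_sd, sd_floor) * infl
    mask = (curve.rel_time >= analysis_window[0]) & (curve.rel_time < analysis_window[1])
    t = curve.rel_time[mask]
    dev = curve.mean_rate[mask] - curve.baseline_mean

    over2 = np.abs(dev) >= 2 * sd
    runs = _contiguous_runs(over2)
    min_len = int(round(MIN_RUN_S / GRID_DT))
    qualifying: list[tuple[int, int]] = []
    for a, b in runs:  # half-open sample run [a, b)
        if b - a < min_len:
            continue
        if np.any(np.abs(dev[a:b]) > 3 * sd):
            qualifying.append((a, b))

    if not qualifying:
        return ResponseCall(False, "none", None)

    signs = {1 if dev[a:b].mean() > 0 else -1 for a, b in qualifying}
    sign = "dual" if len(signs) == 2 else ("excitatory" if 1 in signs else "inhibitory")
    a0, b0 = qualifying[0]
    cross = a0 + int(np.argmax(np.abs(dev[a0:b0]) > 3 * sd))
    intervals = [(float(t[a]), float(t[b - 1] + GRID_DT)) for a, b in qualifying]
    return ResponseCall(True, sign, float(t[cross]), intervals)


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


def classify_cell(call_sleep: ResponseCall, call_wake: ResponseCall) -> CellCategory:
    """Five-way state-dependence classification of one unit."""
    s, w = call_sleep.significant, call_wake.significant
    if s and not w:
        cat = "sleep_only"
    elif w and not s:
        cat = "wake_only"
    elif s and w:
        cat = "both_opposite" if call_sleep.sign != call_wake.sign else "both_same"
    else:
        cat = "none"
    latency_differs = bool(
        s
        and w
        and call_sleep.onset_latency is not None
        and call_wake.onset_latency is not None
        and abs(call_sleep.onset_latency - call_wake.onset_latency) > 0.050
    )
    return CellCategory(cat, latency_differs)


def tabulate_cells(
    categories: dict[str, list[CellCategory]],
) -> pd.DataFrame:
    """Population summary table: one column per group, counts per category.

    Rows: recorded, responded, the four responsive categories, none.
    Responders partition into the four responsive categories by construction.
    """
    rows = {}
    for group, cats in categories.items():
        counts = {c: 0 for c in CATEGORIES}
        for c in cats:
            counts[c.category] += 1
        responded = sum(counts[c] for c in CATEGORIES if c != "none")
        rows[group] = {
            "recorded": len(cats),
            "responded": responded,
            "sleep_only": counts["sleep_only"],
            "wake_only": counts["wake_only"],
            "both_opposite": counts["both_opposite"],
            "both_same": counts["both_same"],
            "none": counts["none"],
        }
    return pd.DataFrame(rows)
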