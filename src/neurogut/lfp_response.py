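"""Evoked local field potential detection and state comparison.

Detection uses the residual orthogonality test (ROT): after per-trial linear
detrending within the analysis window, every unordered pair of trials
``(i, j)`` contributes the point-to-point product sum

    s_ij = sum_t x_i(t) * x_j(t).

A stimulus-locked component common to the trials makes E[s_ij] equal the
energy of that component, so the mean of all pair sums is positive; for
trials that are pure noise the pair sums scatter around zero.  The mean of
``{s_ij}`` is compared to zero with a one-sample t-test.  The verdict is
one-sided (a *positive* mean indicates a response); the two-sided p is also
reported.

For sites responsive in both vigilance states, response magnitude is compared
between states: per state, the absolute extremum of the trial-averaged
z-scored signal inside the analysis window defines a peak time, each trial is
averaged over the 40 ms window centred there, and the two per-trial samples
are compared with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_signals import (
    DegenerateDataError,
    EpochMatrix,
    InsufficientDataError,
)

#: analysis window: 500 ms starting 40 ms after stimulus onset, skipping the
#: artifact-blanked interval around the stimulus train
ROT_WINDOW = (0.040, 0.540)

#: half-width of the peak-amplitude averaging window (total 40 ms)
PEAK_HALFWIDTH = 0.020


@dataclass
class RotResult:
    """Outcome of the residual orthogonality test for one site/state."""

    n_trials: int
    n_pairs: int
    pair_mean: float
    pair_mean_per_sample: float
    t_stat: float
    p_value: float          # one-sided (positive mean)
    p_two_sided: float
    window: tuple[float, float]

    def responsive(self, alpha: float = 0.05) -> bool:
        return self.pair_mean > 0 and self.p_value < alpha


@dataclass
class AmplitudeComparison:
    peak_time: dict[str, float]            # state -> peak time (s)
    amplitudes: dict[str, np.ndarray]      # state -> per-trial 40 ms mean z
    p_value: float
    direction: str                         # sleep_larger / wake_larger / none
    clipped: dict[str, bool]               # peak window truncated?


def _window_mask(rel_time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (rel_time >= window[0]) & (rel_time < window[1])


def detrend_trials(epochs: EpochMatrix, window: tuple[float, float]) -> EpochMatrix:
    """Remove each trial's least-squares straight line within ``window``.

    Returns the matrix restricted to the window with per-trial zero mean and
    zero linear trend.
    """
    mask = _window_mask(epochs.rel_time, window)
    if mask.sum() < 3:
        raise ValueError("detrend window must contain at least 3 samples")
    t = epochs.rel_time[mask]
    X = epochs.data[:, mask]
    # least-squares line per row via the design matrix [1, t]
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)
    out = epochs.select(np.ones(epochs.n_trials, dtype=bool))
    out.data = X - (A @ coef).T
    out.rel_time = t.copy()
    return out


def pair_sums(data: np.ndarray) -> np.ndarray:
    """All unordered pairwise product-sums ``s_ij = <x_i, x_j>``, i < j."""
    gram = data @ data.T
    iu = np.triu_indices(data.shape[0], k=1)
    return gram[iu]


def rot_test(
    epochs: EpochMatrix,
    window: tuple[float, float] = ROT_WINDOW,
    detrend: bool = True,
) -> RotResult:
    """Residual orthogonality test on (detrended) trials within ``window``."""
    if epochs.n_trials < 3:
        raise InsufficientDataError(
            f"ROT requires >= 3 trials, got {epochs.n_trials}"
        )
    windowed = detrend_trials(epochs, window) if detrend else _restrict(epochs, window)
    if np.any(windowed.data.std(axis=1) == 0):
        raise DegenerateDataError("zero-variance trial in ROT window")
    s = pair_sums(windowed.data)
    n = windowed.n_trials
    t_stat, p_two = stats.ttest_1samp(s, 0.0)
    p_one = p_two / 2.0 if t_stat > 0 else 1.0 - p_two / 2.0
    return RotResult(
        n_trials=n,
        n_pairs=s.size,
        pair_mean=float(s.mean()),
        pair_mean_per_sample=float(s.mean() / windowed.rel_time.size),
        t_stat=float(t_stat),
        p_value=float(p_one),
        p_two_sided=float(p_two),
        window=window,
    )


def _restrict(epochs: EpochMatrix, window: tuple[float, float]) -> EpochMatrix:
    mask = _window_mask(epochs.rel_time, window)
    out = epochs.select(np.ones(epochs.n_trials, dtype=bool))
    out.data = epochs.data[:, mask]
    out.rel_time = epochs.rel_time[mask]
    return out


def compare_peak_amplitude(
    z_sleep: EpochMatrix,
    z_wake: EpochMatrix,
    window: tuple[float, float] = ROT_WINDOW,
    alpha: float = 0.05,
) -> AmplitudeComparison:
    """Compare evoked-response magnitudes between sleep and wakefulness.

    Inputs must already be z-scored to their pre-stimulus baselines; the
    caller is responsible for gating on a significant ROT in both states.
    Per-trial magnitudes are the absolute values of the 40 ms window means,
    so negative-going responses compare on equal footing.
    """
    peak_time: dict[str, float] = {}
    amplitudes: dict[str, np.ndarray] = {}
    clipped: dict[str, bool] = {}
    for state, ep in (("SWS", z_sleep), ("WAKE", z_wake)):
        if ep.n_trials < 1:
            raise InsufficientDataError(f"no trials for state {state}")
        mask = _window_mask(ep.rel_time, window)
        mean_curve = ep.data[:, mask].mean(axis=0)
        t_win = ep.rel_time[mask]
        t_peak = float(t_win[np.argmax(np.abs(mean_curve))])
        lo, hi = t_peak - PEAK_HALFWIDTH, t_peak + PEAK_HALFWIDTH
        clip = lo < window[0] or hi > window[1]
        lo, hi = max(lo, window[0]), min(hi, window[1])
        pk = (ep.rel_time >= lo) & (ep.rel_time < hi)
        peak_time[state] = t_peak
        amplitudes[state] = ep.data[:, pk].mean(axis=1)
        clipped[state] = clip

    a_sleep = np.abs(amplitudes["SWS"])
    a_wake = np.abs(amplitudes["WAKE"])
    _, p = stats.ranksums(a_sleep, a_wake)
    direction = "none"
    if p < alpha:
        direction = "sleep_larger" if np.median(a_sleep) > np.median(a_wake) else "wake_larger"
    return AmplitudeComparison(
        peak_time=peak_time,
        amplitudes=amplitudes,
        p_value=float(p),
        direction=direction,
        clipped=clipped,
    )
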