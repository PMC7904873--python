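"""Domain containers and shared preprocessing for stimulus-locked analyses.

The analyses in this package all start from the same four ingredients: a
uniformly sampled continuous recording (LFP, EEG or gut myoelectric signal),
a train of stimulus onsets with per-event artifact flags, a hypnogram of
WAKE/SWS intervals, and (for unit analyses) sorted spike times.  This module
defines those containers and the preprocessing every stage shares: zero-phase
band-pass filtering, stimulus-locked epoching, trial exclusion by vigilance
state and artifact, and per-trial baseline z-scoring.

Conventions
-----------
* All times are seconds; sample ``k`` of a recording occurs at
  ``start_time + k / rate``.
* Analysis windows are half-open ``[start, end)`` on the sample grid;
  stimulus onset is relative time 0 and belongs to the post-stimulus side.
* No operation mutates its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

WAKE = "WAKE"
SWS = "SWS"
STATES = (WAKE, SWS)

CHANNEL_ROLES = ("LFP", "EEG", "GUT", "OTHER")


class InvalidBandError(ValueError):
    """Requested filter band is impossible at the recording's rate."""


class TooShortError(ValueError):
    """Recording shorter than the filter warm-up region."""


class InsufficientDataError(ValueError):
    """Not enough trials/events/windows for the requested statistic."""


class DegenerateDataError(ValueError):
    """Zero-variance input where variance is required (e.g. flat baseline)."""


@dataclass
class ContinuousRecording:
    """Uniformly sampled signal with a sampling rate and channel role."""

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    channel: str = "OTHER"
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.channel not in CHANNEL_ROLES:
            raise ValueError(f"channel must be one of {CHANNEL_ROLES}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate


@dataclass
class EventSeries:
    """Stimulus onset times with per-event artifact flags."""

    onsets: np.ndarray
    artifact_flag: np.ndarray | None = None
    label: str = "stim"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.artifact_flag is None:
            self.artifact_flag = np.zeros(self.onsets.size, dtype=bool)
        self.artifact_flag = np.asarray(self.artifact_flag, dtype=bool)
        if self.artifact_flag.size != self.onsets.size:
            raise ValueError("artifact_flag length must match onsets")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class StateHypnogram:
    """Ordered, non-overlapping WAKE/SWS intervals ``(start, end, state)``."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        clean = []
        for start, end, state in self.intervals:
            start, end = float(start), float(end)
            if not end > start:
                raise ValueError(f"interval ({start}, {end}) has end <= start")
            if start < prev_end:
                raise ValueError("intervals must be ordered and non-overlapping")
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
            clean.append((start, end, state))
            prev_end = end
        self.intervals = clean

    @property
    def span(self) -> tuple[float, float]:
        if not self.intervals:
            return (0.0, 0.0)
        return (self.intervals[0][0], self.intervals[-1][1])

    def state_at(self, t: float) -> str | None:
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        return None

    def interval_index(self, t: float) -> int | None:
        """Index of the interval containing t (closed at both ends)."""
        for i, (start, end, _) in enumerate(self.intervals):
            if start <= t <= end:
                return i
        return None

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class EpochMatrix:
    """Trials x samples matrix locked to stimulus onsets.

    ``rel_time`` is the shared half-open time axis relative to onset;
    ``trial_ids`` index back into the originating :class:`EventSeries`.
    """

    data: np.ndarray
    rel_time: np.ndarray
    rate: float
    trial_state: list[str | None] = field(default_factory=list)
    trial_ids: list[int] = field(default_factory=list)
    dropped_events: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.rel_time = np.asarray(self.rel_time, dtype=float)
        if self.data.size and self.data.shape[1] != self.rel_time.size:
            raise ValueError("rel_time length must match data columns")
        if not self.trial_state:
            self.trial_state = [None] * self.n_trials
        if not self.trial_ids:
            self.trial_ids = list(range(self.n_trials))
        if len(self.trial_state) != self.n_trials:
            raise ValueError("one state label per trial required")
        if len(self.trial_ids) != self.n_trials:
            raise ValueError("one trial id per trial required")

    @property
    def n_trials(self) -> int:
        return 0 if self.data.size == 0 else self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochMatrix":
        mask = np.asarray(mask, dtype=bool)
        return EpochMatrix(
            data=self.data[mask],
            rel_time=self.rel_time.copy(),
            rate=self.rate,
            trial_state=[s for s, m in zip(self.trial_state, mask) if m],
            trial_ids=[i for i, m in zip(self.trial_ids, mask) if m],
            dropped_events=list(self.dropped_events),
        )

    def by_state(self, state: str) -> "EpochMatrix":
        return self.select(np.array([s == state for s in self.trial_state]))


@dataclass
class SpikeTrain:
    """Sorted spike event times for one unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_FILTER_ORDER = 4  # Butterworth, applied forward-backward (zero phase)


def bandpass(rec: ContinuousRecording, lo: float, hi: float) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (low-pass when ``lo == 0``).

    Filtering runs forward and backward (``sosfiltfilt``), so no group delay
    is introduced; output has identical rate and length.
    """
    nyq = rec.rate / 2.0
    if not (0 <= lo < hi):
        raise InvalidBandError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    if hi > nyq:
        raise InvalidBandError(f"high edge {hi} Hz above Nyquist {nyq} Hz")
    if lo == 0:
        sos = signal.butter(_FILTER_ORDER, hi, btype="lowpass", fs=rec.rate, output="sos")
    else:
        sos = signal.butter(_FILTER_ORDER, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    # sosfiltfilt pads by 3 * (max(len(a), len(b)) - 1) per section internally
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise TooShortError(
            f"recording of {rec.n_samples} samples shorter than filter warm-up ({padlen})"
        )
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def extract_epochs(
    rec: ContinuousRecording,
    events: EventSeries,
    window: tuple[float, float],
) -> EpochMatrix:
    """Cut stimulus-locked epochs ``[onset - pre, onset + post)``.

    Events whose window leaves the recording are dropped and reported in
    ``dropped_events``.  No resampling: rows are verbatim slices of the
    recording, so epoching is exactly invertible on the retained spans.
    """
    pre_s, post_s = float(window[0]), float(window[1])
    if pre_s + post_s <= 0:
        raise ValueError(f"invalid window ({pre_s}, {post_s}): length must be > 0")
    n_pre = int(round(pre_s * rec.rate))
    n_post = int(round(post_s * rec.rate))
    n_samp = n_pre + n_post
    rel_time = (np.arange(n_samp) - n_pre) / rec.rate

    rows, ids, dropped = [], [], []
    for i, onset in enumerate(events.onsets):
        k0 = int(round((onset - rec.start_time) * rec.rate)) - n_pre
        if k0 < 0 or k0 + n_samp > rec.n_samples:
            dropped.append(i)
            continue
        rows.append(rec.samples[k0 : k0 + n_samp])
        ids.append(i)

    data = np.vstack(rows) if rows else np.empty((0, n_samp))
    return EpochMatrix(
        data=data,
        rel_time=rel_time,
        rate=rec.rate,
        trial_state=[None] * len(ids),
        trial_ids=ids,
        dropped_events=dropped,
    )


def exclude_trials(
    epochs: EpochMatrix,
    hypnogram: StateHypnogram,
    events: EventSeries,
) -> tuple[EpochMatrix, dict[int, str]]:
    """Drop artifact trials and trials not confined to one vigilance state.

    A trial survives when its full ``[onset - pre, onset + post]`` span lies
    inside a single hypnogram interval and its event is not artifact-flagged.
    Returns the retained matrix (``trial_state`` filled from the hypnogram)
    plus ``{event_index: reason}`` for every excluded trial, reason in
    ``{"artifact", "state_change", "unstaged"}``.
    """
    if epochs.n_trials and max(epochs.trial_ids) >= len(events):
        raise ValueError("epochs trial_ids do not match events")
    pre = -epochs.rel_time[0] if epochs.rel_time.size else 0.0
    post = (epochs.rel_time[-1] + 1.0 / epochs.rate) if epochs.rel_time.size else 0.0

    keep = np.zeros(epochs.n_trials, dtype=bool)
    states: list[str] = []
    reasons: dict[int, str] = {}
    for row, ev_idx in enumerate(epochs.trial_ids):
        if events.artifact_flag[ev_idx]:
            reasons[ev_idx] = "artifact"
            continue
        onset = events.onsets[ev_idx]
        t0, t1 = onset - pre, onset + post
        i0 = hypnogram.interval_index(t0)
        i1 = hypnogram.interval_index(t1)
        if i0 is not None and i0 == i1:
            keep[row] = True
            states.append(hypnogram.intervals[i0][2])
        elif i0 is None and i1 is None and not any(
            start < t1 and end > t0 for start, end, _ in hypnogram.intervals
        ):
            reasons[ev_idx] = "unstaged"
        else:
            reasons[ev_idx] = "state_change"

    retained = epochs.select(keep)
    retained.trial_state = states
    return retained, reasons


def zscore_to_baseline(
    epochs: EpochMatrix, baseline: tuple[float, float] = (-0.5, 0.0)
) -> EpochMatrix:
    """Z-score each trial to its own pre-stimulus baseline.

    Each row becomes ``(x - mean_b) / sd_b`` with the mean and SD taken over
    the half-open baseline window of that same trial.
    """
    t0, t1 = baseline
    mask = (epochs.rel_time >= t0) & (epochs.rel_time < t1)
    if not mask.any():
        raise ValueError(f"baseline window ({t0}, {t1}) outside rel_time")
    base = epochs.data[:, mask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=0, keepdims=True)
    # relative tolerance: a numerically constant baseline has sd ~ eps * |mean|
    tol = 1e-12 * np.maximum(1.0, np.abs(mu.ravel()))
    flat = np.nonzero(sd.ravel() <= tol)[0]
    if flat.size:
        bad = [epochs.trial_ids[i] for i in flat]
        raise DegenerateDataError(f"zero baseline SD in trial(s) {bad}")
    out = epochs.select(np.ones(epochs.n_trials, dtype=bool))
    out.data = (epochs.data - mu) / sd
    return out
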