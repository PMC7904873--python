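"""File readers/writers and the run configuration.

On-disk formats are tab-separated text with a header line; times in
seconds, '.' decimal.  Continuous recordings are two columns
``time_s<TAB>value`` (rate inferred from the time column and validated
uniform); events are ``onset_s<TAB>artifact<TAB>label``; spikes are
``unit_id<TAB>time_s``; hypnograms are ``start_s<TAB>end_s<TAB>state``.
EDF recordings are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_signals import (
    ContinuousRecording,
    EventSeries,
    SpikeTrain,
    StateHypnogram,
)

_REL_TOL = 1e-6  # relative tolerance on sample spacing uniformity


def write_recording(path: str | Path, rec: ContinuousRecording) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tvalue\n")
        for t, v in zip(rec.times, rec.samples):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def read_recording(
    path: str | Path,
    format: str = "delimited",
    channel: str = "OTHER",
    label: str | None = None,
    rate: float | None = None,
) -> ContinuousRecording:
    """Read a continuous recording; never resamples silently.

    For delimited input the rate is inferred from the time column and every
    inter-sample gap is checked against it (relative tolerance 1e-6); a
    declared ``rate`` is cross-checked the same way.  For EDF input the
    channel is selected by ``label``.
    """
    if format == "EDF":
        return _read_edf(path, channel=channel, label=label)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"malformed recording file {path}: need 2 columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("recording must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.nonzero(dt <= 0)[0][0]) + 1
        raise ValueError(f"non-monotone time column at row {bad}")
    dt0 = float(np.median(dt))  # robust spacing: localises isolated gaps
    off = np.abs(dt - dt0) > _REL_TOL * dt0
    if off.any():
        bad = int(np.nonzero(off)[0][0]) + 1
        raise ValueError(f"non-uniform sampling at row {bad}: gap {dt[bad - 1]:g} s")
    inferred = 1.0 / dt0
    if rate is not None and abs(inferred - rate) > _REL_TOL * rate:
        raise ValueError(f"declared rate {rate} Hz inconsistent with timestamps ({inferred:g} Hz)")
    return ContinuousRecording(
        v, inferred, start_time=float(t[0]), channel=channel, label=label or ""
    )


def _read_edf(path: str | Path, channel: str, label: str | None) -> ContinuousRecording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on environment
        raise ImportError("EDF input requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [label] if label else [raw.ch_names[0]]
    data = raw.get_data(picks=picks)[0]
    return ContinuousRecording(
        data, float(raw.info["sfreq"]), start_time=0.0, channel=channel, label=picks[0]
    )


def write_events(path: str | Path, events: EventSeries) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\tartifact\tlabel\n")
        for t, a in zip(events.onsets, events.artifact_flag):
            fh.write(f"{float(t)!r}\t{int(a)}\t{events.label}\n")


def read_events(path: str | Path) -> EventSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        return EventSeries(np.array([]))
    label = str(df["label"].iloc[0]) if "label" in df else "stim"
    return EventSeries(
        df["onset_s"].to_numpy(dtype=float),
        df["artifact"].to_numpy(dtype=int).astype(bool) if "artifact" in df else None,
        label=label,
    )


def write_hypnogram(path: str | Path, hyp: StateHypnogram) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tstate\n")
        for start, end, state in hyp.intervals:
            fh.write(f"{float(start)!r}\t{float(end)!r}\t{state}\n")


def read_hypnogram(path: str | Path) -> StateHypnogram:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return StateHypnogram(
        [(float(r.start_s), float(r.end_s), str(r.state)) for r in df.itertuples()]
    )


def write_spikes(path: str | Path, trains: list[SpikeTrain]) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\ttime_s\n")
        for train in trains:
            for t in train.times:
                fh.write(f"{train.unit_id}\t{float(t)!r}\n")


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    trains = []
    for unit, grp in df.groupby("unit_id", sort=True):
        trains.append(SpikeTrain(str(unit), grp["time_s"].to_numpy(dtype=float)))
    return trains


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run (YAML round-trippable)."""

    lfp_path: str | None = None
    eeg_path: str | None = None
    gut_path: str | None = None
    spikes_path: str | None = None
    events_path: str | None = None
    hypnogram_path: str | None = None
    out_dir: str = "out"
    seed: int = 0
    alpha: float = 0.05
    baseline_s: float = 0.5
    rot_window: tuple[float, float] = (0.040, 0.540)
    spike_window: tuple[float, float] = (0.040, 0.500)
    kernel_sigma: float = 0.020
    staging_window_s: float = 10.0
    disturbance_window_s: float = 10.0
    nw: float = 3.0
    n_tapers: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.baseline_s <= 0:
            raise ValueError("baseline must be positive")
        for name in ("rot_window", "spike_window"):
            w = tuple(float(x) for x in getattr(self, name))
            if w[1] <= w[0]:
                raise ValueError(f"{name} must have end > start")
            setattr(self, name, w)
        if self.n_tapers > 2 * self.nw - 1:
            raise ValueError("n_tapers must be <= 2*NW - 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["rot_window"] = list(d["rot_window"])
        d["spike_window"] = list(d["spike_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for name in ("rot_window", "spike_window"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of inputs and analysis parameters, stamped into outputs.

        The output directory is excluded: where results land does not change
        what they are.
        """
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d["rot_window"] = list(d["rot_window"])
        d["spike_window"] = list(d["spike_window"])
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
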