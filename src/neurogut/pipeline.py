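"""Stage orchestration: file inputs -> per-site/unit results -> reports.

``run_pipeline`` ties the stages together for file-based runs; the
``analyze_*`` helpers are the same entry points operating on in-memory
objects, which tests and simulations call directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ngio
from .core_signals import (
    ContinuousRecording,
    EventSeries,
    InsufficientDataError,
    SpikeTrain,
    StateHypnogram,
    SWS,
    WAKE,
    exclude_trials,
    extract_epochs,
    zscore_to_baseline,
)
from .lfp_response import AmplitudeComparison, RotResult, compare_peak_amplitude, rot_test
from .myoelectric import MyoSessionResult, MyoWindows, analyze_session
from .report_stats import cell_report
from .spike_response import (
    ResponseCall,
    classify_cell,
    detect_response,
    spike_density,
)
from .vigilance import BandSet, compare_states, disturbance_test

log = logging.getLogger("neurogut")


def split_events_by_state(
    events: EventSeries, hypnogram: StateHypnogram, margin: tuple[float, float]
) -> dict[str, EventSeries]:
    """Artifact-free events whose [onset-pre, onset+post] span sits in one state."""
    out = {}
    for state in (SWS, WAKE):
        keep = []
        for onset, bad in zip(events.onsets, events.artifact_flag):
            if bad:
                continue
            i0 = hypnogram.interval_index(onset - margin[0])
            i1 = hypnogram.interval_index(onset + margin[1])
            if i0 is not None and i0 == i1 and hypnogram.intervals[i0][2] == state:
                keep.append(onset)
        out[state] = EventSeries(np.asarray(keep), label=events.label)
    return out


def analyze_lfp_site(
    rec: ContinuousRecording,
    events: EventSeries,
    hypnogram: StateHypnogram,
    config: ngio.RunConfig | None = None,
) -> dict:
    """Per-state ROT verdicts plus the amplitude comparison when both respond."""
    cfg = config or ngio.RunConfig()
    pre = cfg.baseline_s
    post = cfg.rot_window[1]
    epochs = extract_epochs(rec, events, (pre, post))
    retained, reasons = exclude_trials(epochs, hypnogram, events)
    log.info(
        "lfp site: %d trials in, %d retained, %d excluded (%s)",
        epochs.n_trials, retained.n_trials, len(reasons),
        dict(pd.Series(list(reasons.values())).value_counts()) if reasons else {},
    )
    result: dict = {"n_excluded": len(reasons), "exclusion_reasons": reasons}
    rots: dict[str, RotResult] = {}
    for state in (SWS, WAKE):
        sub = retained.by_state(state)
        try:
            rots[state] = rot_test(sub, cfg.rot_window)
        except InsufficientDataError as err:
            log.info("lfp site, state %s: %s", state, err)
    result["rot"] = rots
    both = all(s in rots and rots[s].responsive(cfg.alpha) for s in (SWS, WAKE))
    result["amplitude"] = None
    if both:
        z = zscore_to_baseline(retained, (-cfg.baseline_s, 0.0))
        result["amplitude"] = compare_peak_amplitude(
            z.by_state(SWS), z.by_state(WAKE), cfg.rot_window, cfg.alpha
        )
    return result


def analyze_unit(
    train: SpikeTrain,
    events: EventSeries,
    hypnogram: StateHypnogram,
    config: ngio.RunConfig | None = None,
) -> dict:
    """Per-state rate curves and response calls, plus the cell category."""
    cfg = config or ngio.RunConfig()
    margin = (cfg.baseline_s, cfg.spike_window[1])
    by_state = split_events_by_state(events, hypnogram, margin)
    calls: dict[str, ResponseCall] = {}
    curves = {}
    for state, ev in by_state.items():
        if len(ev) == 0:
            calls[state] = ResponseCall(False, "none", None, degenerate=True)
            continue
        curve = spike_density(train, ev, (-cfg.baseline_s, cfg.spike_window[1]),
                              cfg.kernel_sigma)
        curves[state] = curve
        calls[state] = detect_response(curve, cfg.spike_window)
    category = classify_cell(calls[SWS], calls[WAKE])
    return {"unit_id": train.unit_id, "calls": calls, "curves": curves,
            "category": category}


def run_pipeline(config: ngio.RunConfig) -> dict:
    """Execute every stage for which the config provides inputs.

    Writes ``results.json`` plus TSV summaries into ``config.out_dir``, each
    stamped with the config hash and seed, and returns the result bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed}
    bundle: dict = {"meta": stamp}

    hypnogram = ngio.read_hypnogram(config.hypnogram_path) if config.hypnogram_path else None
    events = ngio.read_events(config.events_path) if config.events_path else None

    if config.eeg_path and hypnogram is not None:
        eeg = ngio.read_recording(config.eeg_path, channel="EEG")
        staging = compare_states(eeg, hypnogram, BandSet(), config.staging_window_s,
                                 config.nw, config.n_tapers, config.alpha)
        bundle["staging"] = {
            b: dataclasses.asdict(r) for b, r in staging.items()
        }
        if events is not None:
            T = config.disturbance_window_s
            sws_events = split_events_by_state(events, hypnogram, (T, T))[SWS]
            try:
                verdict = disturbance_test(eeg, sws_events, hypnogram, BandSet(), T,
                                           config.nw, config.n_tapers, config.alpha)
                bundle["disturbance"] = dataclasses.asdict(verdict)
            except InsufficientDataError as err:
                bundle["disturbance"] = {"error": str(err)}

    if config.lfp_path and events is not None and hypnogram is not None:
        lfp = ngio.read_recording(config.lfp_path, channel="LFP")
        site = analyze_lfp_site(lfp, events, hypnogram, config)
        bundle["lfp"] = {
            "rot": {s: dataclasses.asdict(r) for s, r in site["rot"].items()},
            "amplitude": _amp_dict(site["amplitude"]),
            "n_excluded": site["n_excluded"],
        }

    if config.spikes_path and events is not None and hypnogram is not None:
        trains = ngio.read_spikes(config.spikes_path)
        units = [analyze_unit(tr, events, hypnogram, config) for tr in trains]
        cats = {"all": [u["category"] for u in units]}
        bundle["spikes"] = {
            "units": {
                u["unit_id"]: {
                    "category": u["category"].category,
                    "latency_differs": u["category"].latency_differs,
                    "calls": {s: _call_dict(c) for s, c in u["calls"].items()},
                }
                for u in units
            },
            "table": cell_report(cats).to_dict(),
        }

    if config.gut_path and events is not None:
        gut = ngio.read_recording(config.gut_path, channel="GUT")
        try:
            myo = analyze_session(gut, events, MyoWindows(alpha=config.alpha),
                                  hypnogram, SWS if hypnogram else None)
            bundle["myo"] = _myo_dict(myo)
        except InsufficientDataError as err:
            bundle["myo"] = {"error": str(err)}

    with open(out_dir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True, default=_jsonable)
    _write_tsv_summary(bundle, out_dir / "summary.tsv")
    return bundle


def _call_dict(call: ResponseCall) -> dict:
    return {
        "significant": call.significant,
        "sign": call.sign,
        "onset_latency": call.onset_latency,
        "deviation_intervals": call.deviation_intervals,
        "degenerate": call.degenerate,
    }


def _amp_dict(amp: AmplitudeComparison | None) -> dict | None:
    if amp is None:
        return None
    return {
        "peak_time": amp.peak_time,
        "p_value": amp.p_value,
        "direction": amp.direction,
        "clipped": amp.clipped,
    }


def _myo_dict(myo: MyoSessionResult) -> dict:
    out = {
        "n_events": myo.n_events,
        "simple": {"p": myo.simple.p_value, "direction": myo.simple.direction,
                   "n_events": myo.simple.n_events, "n_dropped": myo.simple.n_dropped},
        "extremum_times": myo.extremum_times,
        "burst": None,
    }
    if myo.burst is not None:
        out["burst"] = {"p": myo.burst.p_value, "direction": myo.burst.direction,
                        "n_events": myo.burst.n_events, "n_dropped": myo.burst.n_dropped}
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _write_tsv_summary(bundle: dict, path: Path) -> None:
    rows = []
    meta = bundle["meta"]
    for stage in ("staging", "disturbance", "lfp", "spikes", "myo"):
        if stage in bundle:
            rows.append({"stage": stage, **meta,
                         "summary": json.dumps(bundle[stage], sort_keys=True,
                                               default=_jsonable)[:2000]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
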