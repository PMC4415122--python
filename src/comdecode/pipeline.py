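"""End-to-end orchestration: simulate -> latents -> decode -> events ->
analyses, with a reproducible run manifest.

The in-memory entry points are :func:`decode_pipeline` (spikes to decoded
traces) and :func:`analyze_session` (the full battery); :func:`run_pipeline`
adds file I/O, digests, and the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .analyses import (
    behavior_choice_stats,
    forced_free_correlation,
    hesitation_rt_comparison,
    indecision_regression,
    zero_delay_rt_comparison,
)
from .decoder import (
    ChoiceDecoder,
    ChoiceTrace,
    LooResult,
    decode_session,
    loo_cross_validate,
    performance_pvalue,
    performance_vs_time,
    train_decoder,
)
from .events import (
    category_frequency_stats,
    detect_events,
    detect_events_loo,
    fit_class_conditionals,
)
from .gpfa import GPFA
from .params import PipelineParams
from .session import SpikeSession, bin_session, save_session
from .synth import GroundTruth, SessionConfig, simulate_session
from .trials import select_trials


@dataclass
class DecodedSession:
    """Latents, decoder, and traces for one session."""

    session: SpikeSession
    params: PipelineParams
    gpfa: GPFA
    latents: Dict[int, np.ndarray]
    times: Dict[int, np.ndarray]
    decoder: ChoiceDecoder
    traces: Dict[int, ChoiceTrace]
    loo: Optional[LooResult] = None


def fit_latents(
    session: SpikeSession,
    params: Optional[PipelineParams] = None,
    gpfa_kwargs: Optional[dict] = None,
) -> Tuple[GPFA, Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    """Fit GPFA on all successful trials and infer their trajectories."""
    params = params or PipelineParams()
    ok = select_trials(session.trials, success=True)
    counts, times, tids = bin_session(session, params, ok)
    kwargs = dict(
        n_latents=params.n_latents,
        bin_width=params.bin_width,
        sqrt_transform=params.sqrt_transform,
        tol=params.gpfa_tol,
        max_iter=params.gpfa_max_iter,
    )
    kwargs.update(gpfa_kwargs or {})
    if kwargs["n_latents"] > session.n_units:
        raise ValueError(
            f"{kwargs['n_latents']} latents requested but only "
            f"{session.n_units} units available"
        )
    model = GPFA(**kwargs)
    model.fit(counts)
    trajs = model.transform(counts)
    latents = {tid: X for tid, X in zip(tids, trajs)}
    times_d = {tid: t for tid, t in zip(tids, times)}
    return model, latents, times_d


def decode_pipeline(
    session: SpikeSession,
    params: Optional[PipelineParams] = None,
    run_loo: bool = True,
    gpfa_kwargs: Optional[dict] = None,
) -> DecodedSession:
    """Spike trains to decoded choice traces (and forced-trial LOO)."""
    params = params or PipelineParams()
    model, latents, times = fit_latents(session, params, gpfa_kwargs)
    dec = train_decoder(latents, times, session.trials, params)
    traces = decode_session(dec, latents, times)
    loo = (
        loo_cross_validate(latents, times, session.trials, params)
        if run_loo
        else None
    )
    return DecodedSession(
        session=session,
        params=params,
        gpfa=model,
        latents=latents,
        times=times,
        decoder=dec,
        traces=traces,
        loo=loo,
    )


#: trial groups entering the event-frequency comparison
EVENT_GROUPS = {
    "free": dict(trial_class="free", no_barrier_change=True),
    "taken_switch": dict(trial_class="encouraged_switch_taken"),
    "untaken_switch": dict(trial_class="encouraged_switch_untaken"),
    "likely_change": dict(trial_class="biasing_likely_change"),
    "unlikely_change": dict(trial_class="biasing_unlikely_change"),
    "free_to_forced": dict(trial_class="free_to_forced"),
}

EVENT_CONTRASTS = (
    ("forced", "free"),
    ("untaken_switch", "taken_switch"),
    ("unlikely_change", "likely_change"),
)


def detect_all_events(ds: DecodedSession) -> Dict[str, dict]:
    """Change-of-mind calls per trial group.

    Forced trials use per-fold leave-one-out decoders and distributions;
    all other groups use the session decoder with class conditionals fit to
    the forced-choice traces.
    """
    params = ds.params
    trials = ds.session.trials
    calls_by_group: Dict[str, dict] = {}
    if ds.loo is not None:
        calls_by_group["forced"] = detect_events_loo(
            ds.latents, ds.times, trials, ds.loo, params
        )
    forced_ids = select_trials(
        trials, success=True, trial_class="forced",
        min_delay=params.min_delay, no_barrier_change=True,
    )
    cond = fit_class_conditionals(
        {tid: ds.traces[tid] for tid in forced_ids if tid in ds.traces},
        trials, params,
    )
    for name, crit in EVENT_GROUPS.items():
        ids = select_trials(trials, success=True, min_delay=params.min_delay,
                            **crit)
        group_traces = {tid: ds.traces[tid] for tid in ids if tid in ds.traces}
        calls_by_group[name] = detect_events(group_traces, cond, trials, params)
    return calls_by_group


def score_against_ground_truth(
    calls_by_group: Dict[str, dict],
    truth: GroundTruth,
) -> dict:
    """Detection confusion counts against injected events."""
    vac_ids = set(truth.trial_ids_with("vacillation"))
    sw_ids = set(truth.trial_ids_with("induced_switch"))
    out = {}
    free_calls = calls_by_group.get("free", {})
    scored_vac = [tid for tid in free_calls if tid in vac_ids]
    out["vacillation"] = {
        "n_truth_scored": len(scored_vac),
        "n_detected": sum(1 for tid in scored_vac if free_calls[tid].is_com),
    }
    forced_calls = calls_by_group.get("forced", {})
    out["forced_false_positives"] = {
        "n_scored": len(forced_calls),
        "n_flagged": sum(1 for c in forced_calls.values() if c.is_com),
    }
    non_event_free = [tid for tid in free_calls if tid not in vac_ids]
    out["free_non_event"] = {
        "n_scored": len(non_event_free),
        "n_flagged": sum(1 for tid in non_event_free if free_calls[tid].is_com),
    }
    switch_groups = ("taken_switch", "likely_change", "free_to_forced")
    scored_sw = [
        tid
        for g in switch_groups
        for tid in calls_by_group.get(g, {})
        if tid in sw_ids
    ]
    out["induced_switch"] = {
        "n_truth_scored": len(scored_sw),
        "n_detected": sum(
            1
            for g in switch_groups
            for tid, c in calls_by_group.get(g, {}).items()
            if tid in sw_ids and c.is_com
        ),
    }
    return out


def analyze_session(
    ds: DecodedSession,
    truth: Optional[GroundTruth] = None,
    mc_reps: Optional[int] = None,
    mc_seed: int = 0,
) -> dict:
    """Run the downstream battery and collect one results dictionary."""
    params = ds.params
    trials = ds.session.trials
    results: dict = {"n_trials": len(trials), "n_units": ds.session.n_units}

    # decoder performance
    if ds.loo is not None:
        results["forced_loo_accuracy"] = ds.loo.accuracy
        n = len(ds.loo.traces)
        n_correct = round(ds.loo.accuracy * n)
        by_id = {t.trial_id: t for t in trials}
        labels = [by_id[tid].choice for tid in ds.loo.traces]
        prevalence = labels.count("R") / len(labels) if labels else 0.5
        results["forced_loo_pvalue"] = performance_pvalue(
            n_correct, n, prevalence=prevalence,
            reps=mc_reps or params.mc_reps, seed=mc_seed,
        )
        results["performance_vs_time"] = performance_vs_time(
            ds.loo.traces, trials, params
        )
    free_ids = select_trials(trials, success=True, trial_class="free",
                             min_delay=params.min_delay,
                             no_barrier_change=True)
    by_id = {t.trial_id: t for t in trials}
    scored = [
        tid for tid in free_ids if tid in ds.traces
    ]
    if scored:
        correct = [
            np.sign(ds.traces[tid].last_point)
            == (1.0 if by_id[tid].choice == "R" else -1.0)
            for tid in scored
        ]
        results["free_final_accuracy"] = float(np.mean(correct))
        results["n_free_scored"] = len(scored)

    # events
    calls = detect_all_events(ds)
    results["event_stats"] = category_frequency_stats(
        calls, contrasts=[c for c in EVENT_CONTRASTS if c[0] in calls and c[1] in calls]
    )
    results["event_calls"] = calls
    if truth is not None:
        results["ground_truth_score"] = score_against_ground_truth(calls, truth)

    # behavioral statistics (each may be unavailable on small sessions)
    for key, fn in (
        ("rt_hesitation", lambda: hesitation_rt_comparison(trials)),
        ("rt_zero_delay", lambda: zero_delay_rt_comparison(trials)),
        ("indecision_regression",
         lambda: indecision_regression(ds.traces, trials, params)),
        ("behavior_choice", lambda: behavior_choice_stats(trials)),
        ("forced_free_correlation",
         lambda: forced_free_correlation(ds.session, ds.traces, params)),
    ):
        try:
            results[key] = fn()
        except ValueError as e:
            results[key] = {"unavailable": str(e)}
    return results


def split_array_traces(
    ds: DecodedSession, arrays: Sequence[str] = ("PMd", "M1")
) -> Dict[str, Dict[int, ChoiceTrace]]:
    """Decode each array separately (own GPFA + decoder) next to the
    combined decode.

    An array with fewer units than the configured latent dimensionality is
    fit with a reduced latent count (with a warning).
    """
    import warnings

    from .decoder import train_decoder as _train

    params = ds.params
    out: Dict[str, Dict[int, ChoiceTrace]] = {"combined": ds.traces}
    for array in arrays:
        sub = ds.session.subset_units(array)
        q = params.n_latents
        if sub.n_units < q:
            warnings.warn(
                f"array {array}: {sub.n_units} units < {q} latents; reducing"
            )
            q = sub.n_units
        model, latents, times = fit_latents(
            sub, params, gpfa_kwargs={"n_latents": q}
        )
        dec = _train(latents, times, sub.trials, params)
        out[array] = decode_session(dec, latents, times)
    return out


# ---------------------------------------------------------------------------
# reporting and manifest

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def make_report(results: dict) -> str:
    """Human-readable summary of a pipeline run."""
    lines = ["# Decoding pipeline report", ""]
    lines.append(
        f"Session: {results.get('n_trials', '?')} trials, "
        f"{results.get('n_units', '?')} units"
    )
    missing = []
    if "forced_loo_accuracy" in results:
        lines.append(
            f"Forced-choice LOO final-point accuracy: "
            f"{results['forced_loo_accuracy']:.3f} "
            f"(p = {results.get('forced_loo_pvalue', float('nan')):.2e})"
        )
    else:
        missing.append("forced LOO decoding")
    if "free_final_accuracy" in results:
        lines.append(
            f"Free-choice final-point accuracy: "
            f"{results['free_final_accuracy']:.3f} "
            f"(n = {results.get('n_free_scored')})"
        )
    ev = results.get("event_stats")
    if ev:
        lines.append("")
        lines.append("Change-of-mind frequencies (Wilson z=1 intervals):")
        for g, d in ev["groups"].items():
            if d["proportion"] is None:
                lines.append(f"  {g}: no trials")
            else:
                lo, hi = d["wilson"]
                lines.append(
                    f"  {g}: {d['k']}/{d['n']} = {d['proportion']:.3f} "
                    f"[{lo:.3f}, {hi:.3f}]"
                )
        for name, t in ev["contrasts"].items():
            if t["p"] is not None:
                lines.append(f"  chi2 {name}: p = {t['p']:.2e}")
    else:
        missing.append("event detection")
    gt = results.get("ground_truth_score")
    if gt:
        lines.append("")
        lines.append("Ground-truth recovery:")
        v = gt["vacillation"]
        lines.append(
            f"  vacillations detected: {v['n_detected']}/{v['n_truth_scored']}"
        )
        f = gt["forced_false_positives"]
        lines.append(
            f"  forced-trial false positives: {f['n_flagged']}/{f['n_scored']}"
        )
    for key, label in (
        ("rt_hesitation", "RT, forced vs untaken switch"),
        ("rt_zero_delay", "RT, zero-delay forced vs free"),
    ):
        d = results.get(key)
        if d and "unavailable" not in d:
            lines.append(
                f"{label}: medians {d['median_a']:.0f} vs {d['median_b']:.0f} ms, "
                f"diff {d['median_diff']:.0f} ms, p = {d['p']:.3g}"
            )
        elif d:
            missing.append(label)
    reg = results.get("indecision_regression")
    if reg and "unavailable" not in reg:
        lo, hi = reg["slope_ci"]
        lines.append(
            f"Indecision regression: slope {reg['slope']:.1f} ms per unit "
            f"decode [95% CI {lo:.1f}, {hi:.1f}], n = {reg['n']}"
        )
    corr = results.get("forced_free_correlation")
    if corr and "unavailable" not in corr:
        lines.append(
            f"Forced/free response correlation: mean r = {corr['mean_r']:.2f} "
            f"over {corr['n_included']} units (sign test p = "
            f"{corr['sign_test_p']:.2e})"
        )
    if missing:
        lines.append("")
        lines.append("Missing sections: " + ", ".join(missing))
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    outdir,
    config: Optional[SessionConfig] = None,
    params: Optional[PipelineParams] = None,
    seed: int = 0,
    mc_reps: Optional[int] = None,
    run_loo: bool = True,
) -> dict:
    """Simulate a session, run every stage, and write outputs + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SessionConfig()
    params = params or PipelineParams()
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "params": _jsonable(params.to_dict()),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "digests": {},
    }
    stage = "simulate"
    try:
        session, truth, _ = simulate_session(config, seed=seed)
        save_session(session, outdir / "fixture.jsonl")
        manifest["stages"].append(stage)

        stage = "decode"
        ds = decode_pipeline(session, params, run_loo=run_loo)
        (outdir / "gpfa_model.json").write_text(json.dumps(ds.gpfa.to_dict()))
        (outdir / "decoder.json").write_text(json.dumps(ds.decoder.to_dict()))
        _write_traces_csv(ds.traces, outdir / "traces.csv")
        manifest["stages"].append(stage)

        stage = "analyze"
        results = analyze_session(ds, truth, mc_reps=mc_reps, mc_seed=seed)
        _write_events_csv(results["event_calls"], outdir / "events.csv")
        summary = {
            k: v for k, v in results.items() if k != "event_calls"
        }
        (outdir / "results.json").write_text(json.dumps(_jsonable(summary)))
        (outdir / "report.txt").write_text(make_report(results))
        manifest["stages"].append(stage)
    except Exception:
        (outdir / "FAILED").write_text(f"failed at stage: {stage}\n")
        raise
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["digests"][f.name] = _sha256(f)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _write_traces_csv(traces: Dict[int, ChoiceTrace], path) -> None:
    import pandas as pd

    rows = []
    for tid, tr in sorted(traces.items()):
        for t, v in zip(tr.times, tr.values):
            rows.append({"trial_id": tid, "time_ms": t, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_events_csv(calls_by_group: Dict[str, dict], path) -> None:
    import pandas as pd

    rows = []
    for group, calls in calls_by_group.items():
        for tid, c in sorted(calls.items()):
            rows.append(
                {
                    "group": group,
                    "trial_id": tid,
                    "is_com": c.is_com,
                    "last_crossing_time": c.last_crossing_time,
                    "direction": c.direction,
                    "sign_change": c.criteria_met[0],
                    "strongly_left": c.criteria_met[1],
                    "strongly_right": c.criteria_met[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
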