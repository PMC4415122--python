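"""Downstream statistics: PSTH similarity, baseline distances, crossing-
window firing rates, RT effects, the indecision regression, split-array
agreement, and behavioral choice tables.

All statistics are invariant to trial and unit ordering; standard tests go
through scipy/statsmodels (Mann-Whitney U, chi-square, sign test, OLS,
two-proportion Z).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .decoder import CHOICE_SIGN, ChoiceTrace
from .events import EventCall
from .params import PipelineParams
from .session import SpikeSession, bin_index_containing, bins_at_or_after
from .trials import TrialRecord, select_trials


# ---------------------------------------------------------------------------
# PSTHs and forced/free similarity

@dataclass
class PSTH:
    """Trial-averaged smoothed firing rates per unit for one condition."""

    times: np.ndarray               # evaluation grid, ms
    mean: np.ndarray                # (n_units, n_times), spikes/s
    sem: np.ndarray                 # (n_units, n_times)
    n_trials: int


def smoothed_rate(
    spikes: np.ndarray,
    grid: np.ndarray,
    sd: float,
    support: Tuple[float, float],
) -> np.ndarray:
    """Gaussian-smoothed single-trial rate (spikes/s) on ``grid``.

    Each spike's kernel is renormalised by its mass inside ``support`` so
    the rate integrates to the spike count (edge correction).
    """
    st = np.asarray(spikes, dtype=float)
    st = st[(st >= support[0]) & (st <= support[1])]
    if st.size == 0:
        return np.zeros_like(grid)
    z = sps.norm.cdf(support[1], loc=st, scale=sd) - sps.norm.cdf(
        support[0], loc=st, scale=sd
    )
    z = np.maximum(z, 1e-12)
    dens = sps.norm.pdf(grid[:, None], loc=st[None, :], scale=sd) / z[None, :]
    return 1000.0 * dens.sum(axis=1)


def compute_psth(
    session: SpikeSession,
    trial_ids: Sequence[int],
    params: Optional[PipelineParams] = None,
    window: Optional[Tuple[float, float]] = None,
    grid_step: float = 10.0,
) -> PSTH:
    """PSTH (mean +/- SEM of smoothed single-trial rates) over a window."""
    params = params or PipelineParams()
    if len(trial_ids) < 2:
        raise ValueError("need at least 2 trials per condition")
    lo, hi = window if window is not None else params.corr_window
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    n_units = session.n_units
    rates = np.empty((len(trial_ids), n_units, grid.size))
    for k, tid in enumerate(trial_ids):
        idx = session.index_of(tid)
        trial = session.trials[idx]
        support = (max(lo - 4 * params.psth_sd, params.epoch_start), min(hi + 4 * params.psth_sd, trial.move_onset))
        for ui in range(n_units):
            rates[k, ui] = smoothed_rate(
                session.spikes[idx][ui], grid, params.psth_sd, support
            )
    mean = rates.mean(axis=0)
    sem = rates.std(axis=0, ddof=1) / math.sqrt(len(trial_ids))
    return PSTH(times=grid, mean=mean, sem=sem, n_trials=len(trial_ids))


def unit_snr(signal: np.ndarray, sems: np.ndarray) -> float:
    """SNR = range of the concatenated response vector / greatest SEM."""
    signal = np.asarray(signal, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if signal.shape != sems.shape:
        raise ValueError("signal and SEM vectors must have the same length")
    noise = float(np.max(sems))
    rng_ = float(np.ptp(signal))
    if noise == 0.0:
        return float("inf")
    return rng_ / noise


def exclude_possible_com(
    traces: Dict[int, ChoiceTrace],
    trial_ids: Sequence[int],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
) -> List[int]:
    """Retain trials whose decoded sign matches the eventual choice at every
    bin past com_window_start (the aggressive PSTH-stage exclusion)."""
    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    missing = [tid for tid in trial_ids if tid not in traces]
    if missing:
        raise ValueError(f"missing decoded traces for trials {missing}")
    kept = []
    for tid in trial_ids:
        tr = traces[tid]
        mask = bins_at_or_after(tr.times, params.com_window_start, params)
        want = CHOICE_SIGN[by_id[tid].choice]
        if np.all(np.sign(tr.values[mask]) == want):
            kept.append(tid)
    return kept


def _condition_ids(
    trials: Sequence[TrialRecord], params: PipelineParams
) -> Dict[str, List[int]]:
    base = dict(
        success=True, min_delay=params.psth_min_delay, no_barrier_change=True
    )
    return {
        f"{cls}_{side}": select_trials(
            trials, trial_class=cls, choice=side, **base
        )
        for cls in ("forced", "free")
        for side in ("L", "R")
    }


def forced_free_correlation(
    session: SpikeSession,
    traces: Dict[int, ChoiceTrace],
    params: Optional[PipelineParams] = None,
) -> dict:
    """Per-unit Pearson r between concatenated forced-[L,R] and free-[L,R]
    mean response vectors, SNR-gated, with an across-unit sign test.

    Possible change-of-mind trials are excluded from the free-trial
    averages before computing the PSTHs.
    """
    params = params or PipelineParams()
    conds = _condition_ids(session.trials, params)
    for side in ("L", "R"):
        key = f"free_{side}"
        have = [tid for tid in conds[key] if tid in traces]
        conds[key] = exclude_possible_com(traces, have, session.trials, params)
    for name, ids in conds.items():
        if len(ids) < 2:
            raise ValueError(f"condition {name} has fewer than 2 trials")
    psths = {name: compute_psth(session, ids, params) for name, ids in conds.items()}

    n_units = session.n_units
    rs, snrs, included = [], [], []
    for ui in range(n_units):
        forced = np.concatenate(
            [psths["forced_L"].mean[ui], psths["forced_R"].mean[ui]]
        )
        free = np.concatenate([psths["free_L"].mean[ui], psths["free_R"].mean[ui]])
        sems = np.concatenate(
            [psths[k].sem[ui] for k in ("forced_L", "forced_R", "free_L", "free_R")]
        )
        snr = unit_snr(np.concatenate([forced, free]), sems)
        snrs.append(snr)
        inc = snr >= params.snr_min
        included.append(inc)
        if inc:
            if np.std(forced) == 0 or np.std(free) == 0:
                rs.append(0.0)
            else:
                rs.append(float(sps.pearsonr(forced, free).statistic))
        else:
            rs.append(float("nan"))
    rs = np.array(rs)
    inc_mask = np.array(included)
    if inc_mask.sum() < 1:
        raise ValueError("no units pass the SNR gate")
    r_inc = rs[inc_mask]
    n_pos = int(np.sum(r_inc > 0))
    sign_p = float(sps.binomtest(n_pos, r_inc.size, 0.5).pvalue)
    return {
        "r": rs,
        "snr": np.array(snrs),
        "included": inc_mask,
        "mean_r": float(np.mean(r_inc)),
        "n_included": int(inc_mask.sum()),
        "sign_test_p": sign_p,
    }


# ---------------------------------------------------------------------------
# tuning / preference consistency

def _epoch_rate(
    session: SpikeSession, tid: int, ui: int, t0: float, t1: float
) -> float:
    idx = session.index_of(tid)
    st = session.spikes[idx][ui]
    t1 = min(t1, session.trials[idx].move_onset)
    if t1 <= t0:
        return float("nan")
    n = int(np.count_nonzero((st >= t0) & (st < t1)))
    return 1000.0 * n / (t1 - t0)


def preference_consistency(
    session: SpikeSession,
    traces: Dict[int, ChoiceTrace],
    params: Optional[PipelineParams] = None,
    alpha: float = 0.05,
) -> dict:
    """Count significantly tuned units whose free-choice preference matches
    their forced-choice preference.

    Tuning: two-sided Wilcoxon rank-sum on per-trial delay-epoch
    (train_start -> Go) mean rates, forced-L vs forced-R, at ``alpha``.
    """
    params = params or PipelineParams()
    conds = _condition_ids(session.trials, params)
    for side in ("L", "R"):
        key = f"free_{side}"
        have = [tid for tid in conds[key] if tid in traces]
        conds[key] = exclude_possible_com(traces, have, session.trials, params)

    def rates(ids: List[int], ui: int) -> np.ndarray:
        by_id = {t.trial_id: t for t in session.trials}
        vals = [
            _epoch_rate(session, tid, ui, params.train_start, by_id[tid].delay)
            for tid in ids
        ]
        return np.array([v for v in vals if not math.isnan(v)])

    n_tuned = 0
    n_maintained = 0
    detail = []
    for ui in range(session.n_units):
        fl = rates(conds["forced_L"], ui)
        fr = rates(conds["forced_R"], ui)
        if fl.size < 2 or fr.size < 2:
            detail.append({"unit": ui, "tuned": False})
            continue
        p = float(sps.ranksums(fl, fr).pvalue)
        tuned = p < alpha
        if not tuned:
            detail.append({"unit": ui, "tuned": False, "p": p})
            continue
        n_tuned += 1
        forced_pref = np.sign(fl.mean() - fr.mean())
        free_l = rates(conds["free_L"], ui)
        free_r = rates(conds["free_R"], ui)
        free_pref = np.sign(free_l.mean() - free_r.mean())
        maintained = bool(forced_pref == free_pref)
        n_maintained += int(maintained)
        detail.append(
            {"unit": ui, "tuned": True, "p": p, "maintained": maintained}
        )
    return {"n_tuned": n_tuned, "n_maintained": n_maintained, "detail": detail}


# ---------------------------------------------------------------------------
# baseline distance

def baseline_distance(
    latents: Dict[int, np.ndarray],
    times: Dict[int, np.ndarray],
    trials: Sequence[TrialRecord],
    event_calls: Dict[int, EventCall],
    group_ids: Dict[str, Sequence[int]],
    params: Optional[PipelineParams] = None,
) -> dict:
    """Euclidean distances from the mean baseline latent state.

    Returns, per group: ``crossings`` (two points per change-of-mind trial,
    flanking the last crossing) and ``all_times`` (every bin >= 160 ms), plus
    the session-wide ``baseline`` distribution (bins in the baseline window
    of all successful trials).
    """
    params = params or PipelineParams()
    lo, hi = params.baseline_window
    ok_ids = set(select_trials(trials, success=True))

    base_states = []
    for tid, X in latents.items():
        if tid not in ok_ids:
            continue
        t = times[tid]
        m = ((t - params.bin_width / 2) >= lo - 1e-9) & (
            (t + params.bin_width / 2) <= hi + 1e-9
        )
        base_states.append(X[m])
    base_states = np.concatenate(base_states, axis=0)
    center = base_states.mean(axis=0)

    def dist(X: np.ndarray) -> np.ndarray:
        return np.linalg.norm(X - center, axis=1)

    out: dict = {
        "baseline_mean_state": center,
        "baseline": dist(base_states),
        "groups": {},
    }
    for name, ids in group_ids.items():
        crossings, all_times = [], []
        for tid in ids:
            X, t = latents[tid], times[tid]
            m = bins_at_or_after(t, params.com_window_start, params)
            all_times.append(dist(X[m]))
            call = event_calls.get(tid)
            if call is not None and call.is_com and call.last_crossing_time is not None:
                before = np.flatnonzero(t < call.last_crossing_time)
                after = np.flatnonzero(t > call.last_crossing_time)
                if before.size and after.size:
                    pair = X[[before[-1], after[0]]]
                    crossings.append(dist(pair))
        out["groups"][name] = {
            "crossings": (
                np.concatenate(crossings) if crossings else np.empty(0)
            ),
            "all_times": (
                np.concatenate(all_times) if all_times else np.empty(0)
            ),
        }
    return out


# ---------------------------------------------------------------------------
# firing rates around crossings

def two_proportion_ztest(k1: int, k2: int, n: int) -> Tuple[float, float]:
    """Z-test comparing two proportions k1/n vs k2/n (pooled SE)."""
    from statsmodels.stats.proportion import proportions_ztest

    stat, p = proportions_ztest([k1, k2], [n, n])
    return float(stat), float(p)


def com_rate_comparison(
    session: SpikeSession,
    event_calls: Dict[int, EventCall],
    comparison_ids: Dict[str, Sequence[int]],
    params: Optional[PipelineParams] = None,
) -> dict:
    """Compare firing rates around change-of-mind crossings to matched
    windows on non-event trials.

    For each unit and each event trial, the rate in the 200 ms window
    centred on the last crossing is compared with the mean rate of the
    comparison left- and right-choice trials over the *same* window.  Units
    are categorised as lower than both comparison rates, between, or higher
    (ties count as between), and lower-vs-higher proportions are compared
    with a two-proportion Z-test.
    """
    params = params or PipelineParams()
    half = params.com_rate_window / 2.0
    event_tids = [
        tid for tid, c in event_calls.items()
        if c.is_com and c.last_crossing_time is not None
    ]
    if not event_tids:
        raise ValueError("no change-of-mind trials with crossings")

    n_units = session.n_units
    ev_rates = np.zeros((len(event_tids), n_units))
    cmp_rates = {k: np.zeros((len(event_tids), n_units)) for k in comparison_ids}
    for j, tid in enumerate(event_tids):
        t_c = event_calls[tid].last_crossing_time
        t0, t1 = t_c - half, t_c + half
        trial = session.trial_by_id(tid)
        if t1 > trial.move_onset or t0 < params.epoch_start:
            warnings.warn(
                f"trial {tid}: crossing window clipped to the trial epoch"
            )
            t0 = max(t0, params.epoch_start)
            t1 = min(t1, trial.move_onset)
        for ui in range(n_units):
            ev_rates[j, ui] = _epoch_rate(session, tid, ui, t0, t1)
        for key, ids in comparison_ids.items():
            for ui in range(n_units):
                vals = [
                    _epoch_rate(session, c_tid, ui, t0, t1) for c_tid in ids
                ]
                vals = [v for v in vals if not math.isnan(v)]
                cmp_rates[key][j, ui] = np.mean(vals) if vals else np.nan

    mean_ev = np.nanmean(ev_rates, axis=0)
    means_cmp = {k: np.nanmean(v, axis=0) for k, v in cmp_rates.items()}
    cmp_stack = np.stack(list(means_cmp.values()))
    lo = cmp_stack.min(axis=0)
    hi = cmp_stack.max(axis=0)
    categories = np.where(
        mean_ev < lo, "lower", np.where(mean_ev > hi, "higher", "between")
    )
    k_lower = int(np.sum(categories == "lower"))
    k_higher = int(np.sum(categories == "higher"))
    if k_lower + k_higher == 0:
        z, p = 0.0, 1.0  # no unit deviated in either direction
    else:
        z, p = two_proportion_ztest(k_lower, k_higher, n_units)
    return {
        "categories": categories,
        "n_lower": k_lower,
        "n_higher": k_higher,
        "n_between": int(np.sum(categories == "between")),
        "z": z,
        "p": p,
        "n_event_trials": len(event_tids),
    }


# ---------------------------------------------------------------------------
# reaction-time statistics

def rt_stats(rts_a: Sequence[float], rts_b: Sequence[float]) -> dict:
    """Medians, median difference, and two-sided Mann-Whitney U p-value.

    Exact p for both groups <= 20 observations, else the tie-corrected
    normal approximation.
    """
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both RT groups must be non-empty")
    method = "exact" if (a.size <= 20 and b.size <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "median_diff": float(np.median(b) - np.median(a)),
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "method": method,
    }


def hesitation_rt_comparison(trials: Sequence[TrialRecord]) -> dict:
    """Forced-choice vs untaken-switch RTs (the hesitation effect)."""
    by_id = {t.trial_id: t for t in trials}
    forced = select_trials(trials, success=True, trial_class="forced",
                           no_barrier_change=True, zero_delay=False)
    untaken = select_trials(trials, success=True,
                            trial_class="encouraged_switch_untaken")
    if not forced or not untaken:
        missing = "forced" if not forced else "encouraged_switch_untaken"
        raise ValueError(f"RT group {missing!r} is empty")
    return rt_stats(
        [by_id[t].rt for t in forced], [by_id[t].rt for t in untaken]
    )


def zero_delay_rt_comparison(trials: Sequence[TrialRecord]) -> dict:
    """Zero-delay forced vs zero-delay free RTs (behavioral indecision)."""
    by_id = {t.trial_id: t for t in trials}
    forced = select_trials(trials, success=True, trial_class="forced",
                           zero_delay=True)
    free = select_trials(trials, success=True, trial_class="free",
                         zero_delay=True)
    if not forced or not free:
        missing = "zero-delay forced" if not forced else "zero-delay free"
        raise ValueError(f"RT group {missing!r} is empty")
    return rt_stats([by_id[t].rt for t in forced], [by_id[t].rt for t in free])


def blocked_plan_rt_comparison(
    traces: Dict[int, ChoiceTrace],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
) -> dict:
    """Free-to-forced trials with a near-Go barrier change, grouped by
    whether the decoded plan at the change pointed at the now-blocked side."""
    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    ids = select_trials(trials, success=True, trial_class="free_to_forced",
                        min_delay=params.min_delay)
    planned_blocked, planned_open = [], []
    for tid in ids:
        t = by_id[tid]
        if t.barrier_change.time < t.delay - params.near_go_margin:
            continue
        if tid not in traces:
            continue
        tr = traces[tid]
        k = np.searchsorted(tr.times, t.barrier_change.time)
        k = min(max(k - 1, 0), tr.times.size - 1)
        sign = np.sign(tr.values[k])
        blocked_sign = CHOICE_SIGN[t.barrier_change.side]
        (planned_blocked if sign == blocked_sign else planned_open).append(t.rt)
    if not planned_blocked or not planned_open:
        raise ValueError("a near-Go free-to-forced RT group is empty")
    return rt_stats(planned_open, planned_blocked)


# ---------------------------------------------------------------------------
# indecision regression

def indecision_regression(
    traces: Dict[int, ChoiceTrace],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
) -> dict:
    """OLS of RT on the choice-aligned decoded value 100 ms after maze onset.

    Uses zero-delay free-choice trials with RT >= 300 ms; the decoded value
    is sign-aligned so that agreement with the eventual reach is positive.
    """
    import statsmodels.api as sm

    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    ids = select_trials(trials, success=True, trial_class="free",
                        zero_delay=True, min_rt=params.indecision_min_rt)
    probe_idx = bin_index_containing(params.indecision_probe, params)
    xs, ys = [], []
    for tid in ids:
        if tid not in traces:
            continue
        tr = traces[tid]
        if probe_idx >= tr.values.size:
            continue  # trial too short to contain the probe bin
        v = tr.values[probe_idx]
        aligned = v * CHOICE_SIGN[by_id[tid].choice]
        xs.append(aligned)
        ys.append(by_id[tid].rt)
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} qualifying zero-delay free trials (need >= 3)"
        )
    X = sm.add_constant(np.asarray(xs))
    fit = sm.OLS(np.asarray(ys), X).fit()
    ci = fit.conf_int(alpha=0.05)
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "slope_p": float(fit.pvalues[1]),
        "n": len(xs),
    }


# ---------------------------------------------------------------------------
# split-array agreement

def trace_agreement(
    a: ChoiceTrace, b: ChoiceTrace, params: Optional[PipelineParams] = None
) -> float:
    """Fraction of bins >= 160 ms with the same decoded sign."""
    params = params or PipelineParams()
    if a.times.size != b.times.size or not np.allclose(a.times, b.times):
        raise ValueError("traces must share the bin grid")
    m = bins_at_or_after(a.times, params.com_window_start, params)
    if not m.any():
        return float("nan")
    return float(np.mean(np.sign(a.values[m]) == np.sign(b.values[m])))


def split_array_agreement(
    traces_by_decoder: Dict[str, Dict[int, ChoiceTrace]],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
) -> dict:
    """Mean per-trial agreement between decoders (e.g. combined/PMd/M1).

    Agreement = fraction of bins at/after 160 ms with equal decoded sign,
    averaged over successful delay >= 300 trials; reported for all trials
    and for free-choice trials only.
    """
    params = params or PipelineParams()
    names = list(traces_by_decoder)
    all_ids = select_trials(trials, success=True, min_delay=params.min_delay)
    free_ids = select_trials(trials, success=True, min_delay=params.min_delay,
                             trial_class="free", no_barrier_change=True)
    out = {"pairs": {}}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a_tr, b_tr = traces_by_decoder[names[i]], traces_by_decoder[names[j]]
            common = [t for t in all_ids if t in a_tr and t in b_tr]
            vals = [trace_agreement(a_tr[t], b_tr[t], params) for t in common]
            vals = [v for v in vals if not math.isnan(v)]
            free = [t for t in free_ids if t in a_tr and t in b_tr]
            fvals = [trace_agreement(a_tr[t], b_tr[t], params) for t in free]
            fvals = [v for v in fvals if not math.isnan(v)]
            out["pairs"][f"{names[i]}-{names[j]}"] = {
                "all_trials": float(np.mean(vals)) if vals else None,
                "free_trials": float(np.mean(fvals)) if fvals else None,
                "n_all": len(vals),
                "n_free": len(fvals),
            }
    return out


# ---------------------------------------------------------------------------
# behavioral choice tables

def behavior_choice_stats(trials: Sequence[TrialRecord]) -> dict:
    """P(choose left) per barrier configuration, and the biasing-change
    shift in choice probability."""
    by_config: Dict[Tuple[str, str], List[str]] = {}
    for t in trials:
        if not t.success or t.barrier_change is not None:
            continue
        key = (t.initial_difficulty["L"], t.initial_difficulty["R"])
        if "blocked" in key:
            continue
        by_config.setdefault(key, []).append(t.choice)
    table = {}
    for key, choices in sorted(by_config.items()):
        n = len(choices)
        k = sum(1 for c in choices if c == "L")
        table["|".join(key)] = {"p_left": k / n, "n": n}

    bias = {}
    for favored in ("L", "R"):
        choices = [
            t.choice
            for t in trials
            if t.success
            and t.trial_class in ("biasing_likely_change", "biasing_unlikely_change")
            and t.barrier_change.side == favored
        ]
        if choices:
            bias[favored] = {
                "p_left": sum(1 for c in choices if c == "L") / len(choices),
                "n": len(choices),
            }
    delta = None
    if "L" in bias and "R" in bias:
        delta = bias["L"]["p_left"] - bias["R"]["p_left"]
    return {"p_left_by_config": table, "biasing": bias, "delta_p_left": delta}
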