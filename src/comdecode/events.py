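"""Conservative change-of-mind detection from decoded choice traces.

A trial (delay >= 300 ms) registers a covert change of mind when, over bins
at/after 160 ms from maze onset, the decoded choice (1) changes sign at
least once, (2) is at some point >= 10x as likely under the forced-*left*
distribution of decoded values as under the forced-right distribution, and
(3) at some point >= 10x as likely under the forced-*right* distribution.
The three criteria may be met at different time points: the decoded choice
must swing from strongly-left to strongly-right or vice versa.

Per-bin class-conditional Gaussians are fit to forced-choice decoded values
on the decoder's bin grid; all bins at/after 600 ms are pooled into one
late bin.  When trials come from leave-one-out cross-validation, the
classifier and the distributions of that fold are used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .decoder import CHOICE_SIGN, ChoiceTrace, LooResult, decode_trace
from .params import PipelineParams
from .session import bins_at_or_after
from .trials import TrialRecord


# ---------------------------------------------------------------------------
# class-conditional model

@dataclass
class ClassConditionalModel:
    """Per-bin Gaussian fits to forced-left/right decoded values.

    ``bin_times`` are bin centers from train_start up to (not including)
    pool_from; the pooled entry covers every bin at/after pool_from.
    """

    bin_times: np.ndarray                  # centers of per-bin entries
    mu: Dict[str, np.ndarray]              # side -> per-bin means
    sd: Dict[str, np.ndarray]              # side -> per-bin SDs (floored)
    pooled_mu: Dict[str, float]
    pooled_sd: Dict[str, float]
    params: PipelineParams = field(default_factory=PipelineParams)
    fold: Optional[int] = None

    def _lookup(self, t: float, side: str) -> Tuple[float, float]:
        w = self.params.bin_width
        if (t - w / 2.0) >= self.params.pool_from - 1e-9:
            return self.pooled_mu[side], self.pooled_sd[side]
        idx = int(np.argmin(np.abs(self.bin_times - t)))
        if abs(self.bin_times[idx] - t) > w / 2.0 + 1e-9:
            raise ValueError(f"time {t} ms is outside the modelled grid")
        return float(self.mu[side][idx]), float(self.sd[side][idx])

    def logpdf(self, t: float, v: float, side: str) -> float:
        mu, sd = self._lookup(t, side)
        return float(sps.norm.logpdf(v, loc=mu, scale=sd))


def fit_class_conditionals(
    forced_traces: Dict[int, ChoiceTrace],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
    fold: Optional[int] = None,
) -> ClassConditionalModel:
    """Fit per-bin Gaussians to forced-choice decoded values, per side.

    SDs use the unbiased (n-1) estimator and are floored at
    ``params.sigma_floor``; a bin with fewer than 2 values per class
    inherits the nearest earlier bin (with a warning).
    """
    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    w = params.bin_width
    n_bins = int(round((params.pool_from - params.train_start) / w))
    bin_times = params.train_start + w * (np.arange(n_bins) + 0.5)

    values: Dict[str, List[List[float]]] = {
        s: [[] for _ in range(n_bins)] for s in ("L", "R")
    }
    pooled: Dict[str, List[float]] = {"L": [], "R": []}
    for tid, trace in forced_traces.items():
        side = by_id[tid].choice
        for t, v in zip(trace.times, trace.values):
            edge = t - w / 2.0
            if edge >= params.pool_from - 1e-9:
                pooled[side].append(float(v))
            elif edge >= params.train_start - 1e-9:
                idx = int(round((t - bin_times[0]) / w))
                values[side][idx].append(float(v))

    for side in ("L", "R"):
        if len(pooled[side]) < 2 and not any(len(v) >= 2 for v in values[side]):
            raise ValueError(f"need >= 2 forced-{side} decoded values")

    mu = {s: np.empty(n_bins) for s in ("L", "R")}
    sd = {s: np.empty(n_bins) for s in ("L", "R")}
    for side in ("L", "R"):
        prev: Optional[Tuple[float, float]] = None
        for i in range(n_bins):
            vals = values[side][i]
            if len(vals) >= 2:
                m = float(np.mean(vals))
                s_ = max(float(np.std(vals, ddof=1)), params.sigma_floor)
                prev = (m, s_)
            else:
                if prev is None:
                    # no earlier bin: borrow the first later fit-able bin
                    later = next(
                        (v for v in values[side][i + 1:] if len(v) >= 2), None
                    )
                    if later is None:
                        later = pooled[side]
                    prev = (
                        float(np.mean(later)),
                        max(float(np.std(later, ddof=1)), params.sigma_floor),
                    )
                warnings.warn(
                    f"bin at {bin_times[i]:.0f} ms has <2 forced-{side} values; "
                    "inheriting neighbouring bin"
                )
            mu[side][i], sd[side][i] = prev

    pooled_mu, pooled_sd = {}, {}
    for side in ("L", "R"):
        vals = pooled[side] if len(pooled[side]) >= 2 else values[side][-1]
        pooled_mu[side] = float(np.mean(vals))
        pooled_sd[side] = max(float(np.std(vals, ddof=1)), params.sigma_floor)

    return ClassConditionalModel(
        bin_times=bin_times, mu=mu, sd=sd,
        pooled_mu=pooled_mu, pooled_sd=pooled_sd, params=params, fold=fold,
    )


def likelihood_ratio(
    model: ClassConditionalModel, t: float, v: float, direction: str
) -> float:
    """Ratio of class-conditional Gaussian densities at value ``v``.

    ``direction="L"`` gives P(v | forced-left) / P(v | forced-right).
    Times before train_start have no model and are rejected.
    """
    params = model.params
    if (t - params.bin_width / 2.0) < params.train_start - 1e-9:
        raise ValueError(f"time {t} ms precedes the modelled window")
    if direction not in ("L", "R"):
        raise ValueError("direction must be 'L' or 'R'")
    other = "R" if direction == "L" else "L"
    return math.exp(model.logpdf(t, v, direction) - model.logpdf(t, v, other))


# ---------------------------------------------------------------------------
# detection

@dataclass
class EventCall:
    trial_id: int
    is_com: bool
    last_crossing_time: Optional[float]
    direction: Optional[str]               # "L->R" or "R->L"
    criteria_met: Tuple[bool, bool, bool]  # (sign change, strongly L, strongly R)


def _window_signs(values: np.ndarray, lead_value: Optional[float]) -> np.ndarray:
    """Signs with the documented tie-break: exact zeros inherit the
    previous bin's sign (``lead_value`` is the bin just before the window)."""
    signs = np.sign(values)
    prev = 0.0 if lead_value is None else float(np.sign(lead_value))
    for i in range(signs.size):
        if signs[i] == 0.0:
            signs[i] = prev
        prev = signs[i]
    return signs


def last_crossing(
    trace: ChoiceTrace, params: Optional[PipelineParams] = None
) -> Tuple[Optional[float], Optional[str]]:
    """Final sign change of the decoded choice at/after com_window_start.

    Returns ``(time, direction)`` with the time at the midpoint of the
    flanking bins, or ``(None, None)`` if the sign never changes.
    """
    params = params or PipelineParams()
    mask = bins_at_or_after(trace.times, params.com_window_start, params)
    if mask.sum() < 2:
        return None, None
    idx = np.flatnonzero(mask)
    lead = trace.values[idx[0] - 1] if idx[0] > 0 else None
    t = trace.times[mask]
    signs = _window_signs(trace.values[mask], lead)
    crossings = np.flatnonzero(
        (signs[1:] != signs[:-1]) & (signs[1:] != 0) & (signs[:-1] != 0)
    )
    if crossings.size == 0:
        return None, None
    k = int(crossings[-1])
    direction = "L->R" if signs[k + 1] > 0 else "R->L"
    return float(0.5 * (t[k] + t[k + 1])), direction


def detect_change_of_mind(
    trace: ChoiceTrace,
    model: ClassConditionalModel,
    params: Optional[PipelineParams] = None,
) -> EventCall:
    """Apply the three-criterion change-of-mind test to one trace."""
    params = params or PipelineParams()
    mask = bins_at_or_after(trace.times, params.com_window_start, params)
    t_win = trace.times[mask]
    v_win = trace.values[mask]
    if t_win.size == 0:
        return EventCall(trace.trial_id, False, None, None, (False, False, False))

    idx = np.flatnonzero(mask)
    lead = trace.values[idx[0] - 1] if idx[0] > 0 else None
    signs = _window_signs(v_win, lead)
    sign_change = bool(
        np.any((signs[1:] != signs[:-1]) & (signs[1:] != 0) & (signs[:-1] != 0))
    )

    # likelihood criteria only apply where a class-conditional model exists
    thr = math.log(params.lr_threshold)
    strongly_l = strongly_r = False
    model_mask = (t_win - params.bin_width / 2.0) >= params.train_start - 1e-9
    for t, v in zip(t_win[model_mask], v_win[model_mask]):
        ll_l = model.logpdf(t, float(v), "L")
        ll_r = model.logpdf(t, float(v), "R")
        if ll_l - ll_r >= thr:
            strongly_l = True
        if ll_r - ll_l >= thr:
            strongly_r = True
        if strongly_l and strongly_r and sign_change:
            break

    is_com = sign_change and strongly_l and strongly_r
    t_cross, direction = last_crossing(trace, params) if sign_change else (None, None)
    return EventCall(
        trial_id=trace.trial_id,
        is_com=is_com,
        last_crossing_time=t_cross,
        direction=direction,
        criteria_met=(sign_change, strongly_l, strongly_r),
    )


def detect_events(
    traces: Dict[int, ChoiceTrace],
    model: ClassConditionalModel,
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
) -> Dict[int, EventCall]:
    """Detect changes of mind on trials with delay >= min_delay."""
    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    out = {}
    for tid, trace in traces.items():
        if by_id[tid].delay < params.min_delay:
            continue
        out[tid] = detect_change_of_mind(trace, model, params)
    return out


def detect_events_loo(
    latents: Dict[int, np.ndarray],
    times: Dict[int, np.ndarray],
    trials: Sequence[TrialRecord],
    loo: LooResult,
    params: Optional[PipelineParams] = None,
) -> Dict[int, EventCall]:
    """Per-fold detection on leave-one-out trials.

    Each held-out trial is scored with that fold's decoder and
    class-conditional distributions fit only to the fold's training trials.
    """
    params = params or PipelineParams()
    out = {}
    for tid, trace in loo.traces.items():
        model = loo.fold_models[tid]
        fold_traces = {
            k: decode_trace(model, latents[k], times[k], k)
            for k in loo.fold_train_ids[tid]
        }
        cond = fit_class_conditionals(fold_traces, trials, params, fold=tid)
        out[tid] = detect_change_of_mind(trace, cond, params)
    return out


# ---------------------------------------------------------------------------
# category statistics

def wilson_interval(k: int, n: int, z: float = 1.0) -> Tuple[float, float]:
    """Wilson score interval; z = 1 gives bounds equivalent to 1 s.e.m."""
    if n == 0:
        raise ValueError("empty group")
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return center - half, center + half


def chi2_2x2(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """2x2 contingency chi-square (no continuity correction)."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table.sum(axis=0) == 0).any():
        # a degenerate margin (e.g. no events anywhere) carries no evidence
        return 0.0, 1.0
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def category_frequency_stats(
    calls_by_group: Dict[str, Dict[int, EventCall]],
    contrasts: Sequence[Tuple[str, str]] = (),
    z: float = 1.0,
) -> dict:
    """Event proportions per trial group with Wilson intervals and the
    requested pairwise chi-square contrasts."""
    groups = {}
    for name, calls in calls_by_group.items():
        n = len(calls)
        k = sum(1 for c in calls.values() if c.is_com)
        entry: dict = {"k": k, "n": n}
        if n == 0:
            entry["proportion"] = None
            entry["wilson"] = None
        else:
            entry["proportion"] = k / n
            entry["wilson"] = wilson_interval(k, n, z=z)
        groups[name] = entry

    tests = {}
    for g1, g2 in contrasts:
        a, b = groups[g1], groups[g2]
        if a["n"] == 0 or b["n"] == 0:
            tests[f"{g1}_vs_{g2}"] = {"chi2": None, "p": None}
            continue
        chi2, p = chi2_2x2(a["k"], a["n"], b["k"], b["n"])
        tests[f"{g1}_vs_{g2}"] = {"chi2": chi2, "p": p}
    return {"groups": groups, "contrasts": tests}
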