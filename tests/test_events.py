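"""Change-of-mind detector: class-conditional fits, likelihood ratios, the
three criteria, crossings, and category statistics."""

import math

import numpy as np
import pytest

from comdecode.decoder import ChoiceTrace
from comdecode.events import (
    EventCall,
    category_frequency_stats,
    detect_change_of_mind,
    fit_class_conditionals,
    last_crossing,
    likelihood_ratio,
    wilson_interval,
)
from comdecode.params import PipelineParams
from comdecode.session import bin_centers
from test_trials import make_trial


def _grid(n_bins=40):
    return bin_centers(n_bins, PipelineParams())  # -290, -270, ... ms


def _trace(values, tid=0):
    values = np.asarray(values, dtype=float)
    return ChoiceTrace(trial_id=tid, times=_grid(values.size), values=values)


def _exact_model(mu_l=-0.9, mu_r=0.9, sd=0.2):
    """Class-conditional model with exact per-bin Gaussians."""
    from comdecode.events import ClassConditionalModel

    params = PipelineParams()
    w = params.bin_width
    n_bins = int(round((params.pool_from - params.train_start) / w))
    bt = params.train_start + w * (np.arange(n_bins) + 0.5)
    return ClassConditionalModel(
        bin_times=bt,
        mu={"L": np.full(n_bins, mu_l), "R": np.full(n_bins, mu_r)},
        sd={"L": np.full(n_bins, sd), "R": np.full(n_bins, sd)},
        pooled_mu={"L": mu_l, "R": mu_r},
        pooled_sd={"L": sd, "R": sd},
        params=params,
    )


def test_class_conditional_mean_and_unbiased_sd():
    params = PipelineParams()
    trials, traces = [], {}
    for i, v in enumerate([0.0, 2.0]):
        trials.append(make_trial(tid=i, delay=900.0, rt=300.0, choice="L",
                                 init=("easy", "blocked")))
        traces[i] = _trace(np.full(40, v), tid=i)
    for i in (2, 3):
        trials.append(make_trial(tid=i, delay=900.0, rt=300.0, choice="R",
                                 init=("blocked", "easy")))
        traces[i] = _trace(np.full(40, -1.0), tid=i)
    model = fit_class_conditionals(traces, trials, params)
    assert np.allclose(model.mu["L"], 1.0)
    assert np.allclose(model.sd["L"], np.std([0.0, 2.0], ddof=1))
    # identical samples: SD floored, not zero
    assert np.all(model.sd["R"] == params.sigma_floor)


def test_late_time_points_share_the_pooled_bin():
    model = _exact_model()
    params = PipelineParams()
    # 610 and 650 ms bin centers are both at/after the 600 ms pooling start
    for side in ("L", "R"):
        assert model._lookup(610.0, side) == model._lookup(650.0, side)
        assert model._lookup(610.0, side) == (
            model.pooled_mu[side], model.pooled_sd[side]
        )


def test_likelihood_ratio_symmetry_and_strength():
    model = _exact_model(mu_l=-1.0, mu_r=1.0, sd=0.2)
    t = 410.0
    # value equidistant from both class means -> ratio ~ 1
    assert likelihood_ratio(model, t, 0.0, "L") == pytest.approx(1.0, rel=1e-9)
    # value at the left mean: overwhelmingly left
    assert likelihood_ratio(model, t, -1.0, "L") > 1e10
    with pytest.raises(ValueError, match="window"):
        likelihood_ratio(model, 0.0, 0.0, "L")


def test_likelihood_ratio_identical_classes_is_unity():
    model = _exact_model(mu_l=0.5, mu_r=0.5, sd=0.3)
    for v in (-1.0, 0.0, 2.0):
        assert likelihood_ratio(model, 410.0, v, "L") == pytest.approx(1.0, rel=1e-9)


def test_constant_trace_is_not_an_event():
    model = _exact_model()
    call = detect_change_of_mind(_trace(np.full(40, 0.8)), model)
    assert not call.is_com
    assert call.criteria_met[0] is False
    assert call.criteria_met[2] is True  # strongly rightward at some point


def test_clear_swing_is_an_event_with_direction():
    model = _exact_model()
    t = _grid(40)
    vals = np.where(t <= 400.0, -0.9, 0.9)
    call = detect_change_of_mind(_trace(vals), model)
    assert call.is_com
    assert call.criteria_met == (True, True, True)
    assert call.direction == "L->R"
    assert call.last_crossing_time == pytest.approx(400.0)


def test_weak_oscillation_crosses_but_is_not_an_event():
    model = _exact_model()
    rng = np.random.default_rng(1)
    vals = 0.05 * np.sign(np.sin(np.arange(40)))  # tiny oscillation around 0
    call = detect_change_of_mind(_trace(vals), model)
    assert call.criteria_met[0] is True
    assert not call.criteria_met[1] and not call.criteria_met[2]
    assert not call.is_com


def test_label_symmetry():
    """Negating traces and swapping class models flips directions only."""
    model = _exact_model()
    swapped = type(model)(
        bin_times=model.bin_times,
        mu={"L": -model.mu["R"], "R": -model.mu["L"]},
        sd={"L": model.sd["R"], "R": model.sd["L"]},
        pooled_mu={"L": -model.pooled_mu["R"], "R": -model.pooled_mu["L"]},
        pooled_sd={"L": model.pooled_sd["R"], "R": model.pooled_sd["L"]},
        params=model.params,
    )
    t = _grid(40)
    vals = np.where(t <= 300.0, -0.8, np.where(t <= 500.0, 0.9, 0.85))
    a = detect_change_of_mind(_trace(vals), model)
    b = detect_change_of_mind(_trace(-vals), swapped)
    assert a.is_com == b.is_com
    assert a.last_crossing_time == b.last_crossing_time
    assert a.direction == "L->R" and b.direction == "R->L"


def test_last_crossing_scan():
    t4 = bin_centers(4, PipelineParams(com_window_start=-300.0))
    params = PipelineParams(com_window_start=-300.0)
    tr = ChoiceTrace(0, t4, np.array([-1.0, -0.5, 0.3, 0.7]))
    tc, direction = last_crossing(tr, params)
    assert tc == pytest.approx(0.5 * (t4[1] + t4[2]))
    assert direction == "L->R"
    # monotone positive: none
    tr2 = ChoiceTrace(0, t4, np.array([0.1, 0.2, 0.3, 0.4]))
    assert last_crossing(tr2, params) == (None, None)
    # two crossings: the later one wins
    tr3 = ChoiceTrace(0, t4, np.array([1.0, -1.0, -0.5, 0.5]))
    tc3, d3 = last_crossing(tr3, params)
    assert tc3 == pytest.approx(0.5 * (t4[2] + t4[3]))
    assert d3 == "L->R"


def test_exact_zero_inherits_previous_sign():
    params = PipelineParams(com_window_start=-300.0)
    t4 = bin_centers(4, params)
    tr = ChoiceTrace(0, t4, np.array([0.5, 0.0, 0.0, 0.2]))
    assert last_crossing(tr, params) == (None, None)


def test_category_stats_wilson_and_contrasts():
    def calls(k, n):
        return {
            i: EventCall(i, i < k, 300.0 if i < k else None,
                         "L->R" if i < k else None, (i < k,) * 3)
            for i in range(n)
        }

    stats = category_frequency_stats(
        {"forced": calls(2, 100), "free": calls(13, 100)},
        contrasts=[("forced", "free")],
    )
    g = stats["groups"]["free"]
    assert g["k"] == 13 and g["n"] == 100
    lo, hi = g["wilson"]
    assert lo < 0.13 < hi
    assert stats["contrasts"]["forced_vs_free"]["p"] < 0.01
    # empty group reported missing
    stats2 = category_frequency_stats({"empty": {}})
    assert stats2["groups"]["empty"]["proportion"] is None


def test_wilson_symmetric_case():
    lo, hi = wilson_interval(5, 10, z=1.0)
    assert (lo + hi) / 2 == pytest.approx(0.5)
    assert wilson_interval(0, 10)[0] == pytest.approx(0.0, abs=1e-12)
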