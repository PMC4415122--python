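"""Statistics battery: PSTH smoothing, SNR gating, trace-based exclusions,
distances, firing-rate categories, RT tests, regression, agreement, and
choice tables."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from comdecode.analyses import (
    baseline_distance,
    behavior_choice_stats,
    com_rate_comparison,
    compute_psth,
    exclude_possible_com,
    indecision_regression,
    rt_stats,
    smoothed_rate,
    trace_agreement,
    two_proportion_ztest,
    unit_snr,
)
from comdecode.decoder import ChoiceTrace
from comdecode.events import EventCall
from comdecode.params import PipelineParams
from comdecode.session import SpikeSession, UnitInfo, bin_centers
from comdecode.trials import BarrierChange
from test_trials import make_trial


# ---------------------------------------------------------------------------
# PSTH smoothing

def test_smoothed_rate_conserves_mass():
    grid = np.arange(-200.0, 300.0 + 1, 1.0)
    spikes = np.array([-150.0, 0.0, 280.0])  # includes a near-edge spike
    rate = smoothed_rate(spikes, grid, 30.0, (-200.0, 300.0))
    integral = np.trapezoid(rate / 1000.0, grid)
    assert integral == pytest.approx(len(spikes), rel=0.01)


def test_smoothed_rate_zero_spikes():
    grid = np.arange(-200.0, 300.0, 10.0)
    assert np.all(smoothed_rate(np.array([]), grid, 30.0, (-200.0, 300.0)) == 0)


def test_single_spike_gives_gaussian_bump():
    grid = np.arange(-200.0, 300.0, 1.0)
    rate = smoothed_rate(np.array([50.0]), grid, 30.0, (-200.0, 300.0))
    peak = grid[np.argmax(rate)]
    assert peak == pytest.approx(50.0, abs=1.0)
    # half-width consistent with a 30 ms SD Gaussian
    assert rate[np.argmin(np.abs(grid - 80.0))] / rate.max() == pytest.approx(
        math.exp(-0.5), rel=0.02
    )


def test_compute_psth_flat_poisson_unit():
    rng = np.random.default_rng(0)
    n_trials, rate_hz = 60, 25.0
    trials, spikes = [], []
    for i in range(n_trials):
        trials.append(make_trial(tid=i, delay=500.0, rt=300.0))
        n = rng.poisson(rate_hz * 1.2)
        spikes.append([np.sort(rng.uniform(-300.0, 900.0, size=n))])
    session = SpikeSession(units=[UnitInfo(0, "PMd")], trials=trials,
                           spikes=spikes, name="flat")
    psth = compute_psth(session, list(range(n_trials)),
                        window=(-100.0, 300.0))
    # mean rate within a few SEM of the true rate across the window
    err = np.abs(psth.mean[0] - rate_hz)
    assert np.mean(err <= 3 * psth.sem[0] + 1.0) > 0.9


def test_compute_psth_requires_two_trials():
    session = SpikeSession(
        units=[UnitInfo(0, "PMd")],
        trials=[make_trial(tid=0)],
        spikes=[[np.array([0.0])]],
        name="one",
    )
    with pytest.raises(ValueError, match="2 trials"):
        compute_psth(session, [0])


# ---------------------------------------------------------------------------
# SNR gate

def test_unit_snr_arithmetic():
    assert unit_snr([0, 8], [2.0, 1.0]) == pytest.approx(4.0)
    assert unit_snr([5, 5, 5], [1.0, 1.0, 1.0]) == 0.0
    assert unit_snr([0, 8], [0.0, 0.0]) == float("inf")
    # scale invariance
    assert unit_snr([0, 16], [4.0, 2.0]) == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# possible-change-of-mind exclusion

def test_exclude_possible_com_matches_pointwise_scan():
    params = PipelineParams()
    rng = np.random.default_rng(1)
    t = bin_centers(40, params)
    trials, traces = [], {}
    for i in range(10):
        choice = "R" if i % 2 == 0 else "L"
        sign = 1.0 if choice == "R" else -1.0
        vals = sign * np.abs(rng.normal(0.5, 0.3, size=40))
        if i in (3, 4, 8):  # plant one opposite-sign point late in the trial
            vals[30] = -sign * 0.2
        trials.append(make_trial(tid=i, choice=choice, delay=600.0, rt=300.0))
        traces[i] = ChoiceTrace(i, t, vals)
    kept = exclude_possible_com(traces, list(range(10)), trials, params)
    # brute-force per-point scan
    want = []
    for i in range(10):
        sign = 1.0 if trials[i].choice == "R" else -1.0
        window = traces[i].values[(t - 10.0) >= 160.0 - 1e-9]
        if np.all(np.sign(window) == sign):
            want.append(i)
    assert kept == want
    assert 3 not in kept and 4 not in kept


def test_exclude_possible_com_missing_trace_errors():
    params = PipelineParams()
    trials = [make_trial(tid=0)]
    with pytest.raises(ValueError, match=r"\[0\]"):
        exclude_possible_com({}, [0], trials, params)


# ---------------------------------------------------------------------------
# baseline distance

def test_baseline_distance_euclidean_arithmetic():
    params = PipelineParams(n_latents=12)
    t = bin_centers(40, params)
    trials = [make_trial(tid=i, delay=500.0, rt=310.0) for i in range(3)]
    base = np.zeros((40, 12))
    latents = {0: base.copy(), 1: base.copy()}
    # trial 2 offset by delta in every dimension
    delta = 0.7
    latents[2] = base + delta
    times = {i: t for i in range(3)}
    calls = {
        2: EventCall(2, True, 400.0, "L->R", (True, True, True)),
    }
    out = baseline_distance(latents, times, trials, calls,
                            {"grp": [2]}, params)
    # baseline points of trials 0/1 are exactly at the mean of 0,0,delta...
    # use a cleaner check: distance of the offset trial's crossing points
    crossings = out["groups"]["grp"]["crossings"]
    assert crossings.shape == (2,)
    center = out["baseline_mean_state"]
    want = np.linalg.norm((base[0] + delta) - center)
    assert np.allclose(crossings, want)
    # and the pure arithmetic: offset by delta in all 12 dims from zero
    assert np.linalg.norm(np.full(12, delta)) == pytest.approx(
        delta * math.sqrt(12)
    )


def test_baseline_distance_no_crossings_empty():
    params = PipelineParams(n_latents=2)
    t = bin_centers(40, params)
    trials = [make_trial(tid=0, delay=500.0, rt=310.0)]
    out = baseline_distance({0: np.zeros((40, 2))}, {0: t}, trials, {},
                            {"grp": [0]}, params)
    assert out["groups"]["grp"]["crossings"].size == 0
    assert out["groups"]["grp"]["all_times"].size > 0


# ---------------------------------------------------------------------------
# crossing-window firing rates

def _rate_session(rates_by_trial, duration=900.0):
    """One unit; trial i fires at a constant rate via regular spacing."""
    trials, spikes = [], []
    for i, r in enumerate(rates_by_trial):
        trials.append(make_trial(tid=i, delay=600.0, rt=300.0))
        if r > 0:
            step = 1000.0 / r
            spikes.append([np.arange(-300.0 + step / 2, duration, step)])
        else:
            spikes.append([np.empty(0)])
    return SpikeSession(units=[UnitInfo(0, "PMd")], trials=trials,
                        spikes=spikes, name="rates")


def test_com_rate_categories_and_tie_rule():
    session = _rate_session([10.0, 20.0, 40.0])  # event, free-L, free-R
    calls = {0: EventCall(0, True, 400.0, "L->R", (True,) * 3)}
    out = com_rate_comparison(session, calls, {"free_L": [1], "free_R": [2]})
    assert out["categories"][0] == "lower"
    session2 = _rate_session([20.0, 20.0, 40.0])  # equal to one comparator
    out2 = com_rate_comparison(session2, calls, {"free_L": [1], "free_R": [2]})
    assert out2["categories"][0] == "between"
    session3 = _rate_session([80.0, 20.0, 40.0])
    out3 = com_rate_comparison(session3, calls, {"free_L": [1], "free_R": [2]})
    assert out3["categories"][0] == "higher"


def test_two_proportion_ztest_closed_form():
    z, p = two_proportion_ztest(37, 27, 100)
    pp = (37 + 27) / 200
    z_hand = (0.37 - 0.27) / math.sqrt(pp * (1 - pp) * (2 / 100))
    assert z == pytest.approx(z_hand, rel=1e-10)
    assert p == pytest.approx(2 * sps.norm.sf(abs(z_hand)), rel=1e-10)


# ---------------------------------------------------------------------------
# RT statistics

def test_rt_stats_exact_small_sample():
    res = rt_stats([1, 2, 3], [4, 5, 6])
    assert res["p"] == pytest.approx(0.1)
    assert res["median_diff"] == pytest.approx(3.0)
    assert res["method"] == "exact"


def test_rt_stats_shift_detected_at_n200():
    rng = np.random.default_rng(2)
    a = rng.normal(300, 40, size=200)
    b = a + 50.0
    res = rt_stats(a, b)
    assert res["method"] == "asymptotic"
    assert res["p"] < 1e-6
    assert res["median_diff"] == pytest.approx(50.0, abs=1.0)


def test_rt_stats_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        rt_stats([], [1.0])


# ---------------------------------------------------------------------------
# indecision regression

def test_indecision_sign_alignment_rule():
    """A left-choice trial with decode -0.5 at the probe contributes an
    aligned value of +0.5."""
    params = PipelineParams()
    t = bin_centers(25, params)
    trials, traces = [], {}
    for i, (choice, v, rt) in enumerate(
        [("L", -0.5, 400.0), ("L", 0.5, 500.0), ("R", 0.5, 400.0),
         ("R", -0.5, 500.0)]
    ):
        trials.append(make_trial(tid=i, delay=0.0, rt=rt, choice=choice))
        vals = np.zeros(25)
        vals[20] = v
        traces[i] = ChoiceTrace(i, t, vals)
    reg = indecision_regression(traces, trials, params)
    # aligned x: +0.5 -> 400, -0.5 -> 500 for both choices
    assert reg["slope"] == pytest.approx(-100.0)
    assert reg["n"] == 4


def test_indecision_requires_three_trials():
    params = PipelineParams()
    t = bin_centers(25, params)
    trials = [make_trial(tid=0, delay=0.0, rt=400.0, choice="R")]
    traces = {0: ChoiceTrace(0, t, np.zeros(25))}
    with pytest.raises(ValueError, match="need >= 3"):
        indecision_regression(traces, trials, params)


# ---------------------------------------------------------------------------
# split-array agreement

def test_trace_agreement_identical_flipped_random():
    params = PipelineParams()
    t = bin_centers(40, params)
    rng = np.random.default_rng(3)
    vals = rng.normal(size=40)
    a = ChoiceTrace(0, t, vals)
    b = ChoiceTrace(0, t, vals.copy())
    c = ChoiceTrace(0, t, -vals)
    assert trace_agreement(a, b, params) == 1.0
    assert trace_agreement(a, c, params) == 0.0
    # independent random signs: agreement near 0.5 over many bins
    t_long = bin_centers(2000, params)
    x = ChoiceTrace(0, t_long, rng.choice([-1.0, 1.0], size=2000))
    y = ChoiceTrace(0, t_long, rng.choice([-1.0, 1.0], size=2000))
    assert trace_agreement(x, y, params) == pytest.approx(0.5, abs=0.04)


# ---------------------------------------------------------------------------
# behavioral choice tables

def test_behavior_choice_stats_counting():
    trials = []
    tid = 0
    for _ in range(60):
        trials.append(make_trial(tid=tid, choice="L")); tid += 1
    for _ in range(40):
        trials.append(make_trial(tid=tid, choice="R")); tid += 1
    out = behavior_choice_stats(trials)
    assert out["p_left_by_config"]["easy|easy"] == {"p_left": 0.6, "n": 100}


def test_behavior_choice_stats_all_left():
    trials = [
        make_trial(tid=0, init=("easy", "hard"), choice="L"),
        make_trial(tid=1, init=("easy", "hard"), choice="L"),
        make_trial(tid=2, init=("hard", "hard"), choice="L"),
    ]
    out = behavior_choice_stats(trials)
    for cell in out["p_left_by_config"].values():
        assert cell["p_left"] == 1.0


def test_behavior_biasing_delta():
    trials = [
        make_trial(tid=0, init=("hard", "easy"), choice="L",
                   change=BarrierChange(300.0, "L", "easy")),
        make_trial(tid=1, init=("hard", "easy"), choice="R",
                   change=BarrierChange(300.0, "L", "easy")),
        make_trial(tid=2, init=("easy", "hard"), choice="R",
                   change=BarrierChange(300.0, "R", "easy")),
    ]
    out = behavior_choice_stats(trials)
    assert out["biasing"]["L"]["p_left"] == 0.5
    assert out["biasing"]["R"]["p_left"] == 0.0
    assert out["delta_p_left"] == pytest.approx(0.5)
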