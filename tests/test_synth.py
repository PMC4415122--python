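"""Synthetic generator: timing distributions, intention logic, spike
emission, determinism, and signal fidelity."""

import numpy as np
import pytest
from scipy import stats as sps

import comdecode as cd
from comdecode.synth import (
    IntentionTrace,
    SessionConfig,
    UnitTuning,
    emit_spikes,
    sample_trial_schedule,
    sample_truncated_exponential,
    sample_tuning,
    simulate_intention,
    truncated_exponential_mean,
)
from comdecode.trials import BarrierChange
from test_trials import make_trial


def test_truncated_exponential_mean_matches_closed_form():
    rng = np.random.default_rng(0)
    x = sample_truncated_exponential(500.0, 1000.0, 100_000, rng)
    want = truncated_exponential_mean(500.0, 1000.0)
    assert want == pytest.approx(343.48, abs=0.01)
    assert np.mean(x) == pytest.approx(want, abs=3.0)


def test_truncated_exponential_limit_recovers_plain_exponential():
    rng = np.random.default_rng(1)
    x = sample_truncated_exponential(500.0, 1e9, 100_000, rng)
    assert np.mean(x) == pytest.approx(500.0, rel=0.02)


def test_default_session_size():
    cfg = SessionConfig()
    rng = np.random.default_rng(2)
    trials = sample_trial_schedule(cfg, rng)
    assert len(trials) == 1302
    assert len(sample_tuning(cfg, rng)) == 101


def test_schedule_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        SessionConfig(p_forced=1.2, p_free=-0.52).class_mix()
    cfg = SessionConfig()
    cfg.p_left_table[("easy", "easy")] = 1.5
    with pytest.raises(ValueError):
        cfg.class_mix()


def test_fixed_seed_reproduces_session_bitwise():
    cfg = cd.desk_config(n_trials=25, n_units=6)
    s1, gt1, _ = cd.simulate_session(cfg, seed=42)
    s2, gt2, _ = cd.simulate_session(cfg, seed=42)
    assert [t.to_dict() for t in s1.trials] == [t.to_dict() for t in s2.trials]
    for a, b in zip(s1.spikes, s2.spikes):
        for sa, sb in zip(a, b):
            assert np.array_equal(sa, sb)
    assert gt1.traces[0].transitions == gt2.traces[0].transitions


def test_free_choice_frequencies_match_configured_table():
    cfg = SessionConfig(n_trials=4000)
    rng = np.random.default_rng(3)
    trials = sample_trial_schedule(cfg, rng)
    free = [t for t in trials if t.trial_class == "free"
            and t.initial_difficulty == {"L": "easy", "R": "easy"}]
    k = sum(1 for t in free if t.choice == "L")
    n = len(free)
    p = cfg.p_left_table[("easy", "easy")]
    # Wilson 99% bounds
    lo, hi = cd.wilson_interval(k, n, z=2.576)
    assert lo <= p <= hi


def test_intention_forced_trial_single_transition():
    cfg = cd.desk_config(p_vac=0.0)
    rng = np.random.default_rng(4)
    t = make_trial(init=("easy", "blocked"), choice="L", delay=600.0)
    tr = simulate_intention(t, cfg, rng)
    assert tr.plans == ["L"]
    assert tr.n_plan_changes() == 0
    assert tr.plan_at(-100.0) == "none"
    assert tr.plan_at(500.0) == "L"


def test_intention_forced_vacillation():
    cfg = cd.desk_config(p_vac=1.0)
    rng = np.random.default_rng(5)
    t = make_trial(init=("easy", "easy"), choice="R", delay=700.0)
    tr = simulate_intention(t, cfg, rng)
    kinds = [e["kind"] for e in tr.events]
    assert kinds.count("vacillation") == 1
    assert tr.plans == ["L", "R"]
    assert tr.final_plan == t.choice


def test_intention_unlucky_free_to_forced_timing():
    cfg = cd.desk_config(replan_jitter=0.0, replan_latency=150.0)
    rng = np.random.default_rng(0)
    t = make_trial(
        init=("easy", "easy"), choice="R", delay=800.0,
        change=BarrierChange(400.0, "L", "blocked"),
    )
    # repeat until the sampled initial plan is the blocked side
    for _ in range(50):
        tr = simulate_intention(
            make_trial(init=("easy", "easy"), choice="R", delay=800.0,
                       change=BarrierChange(400.0, "L", "blocked")),
            cfg, rng,
        )
        if any(e["kind"] == "induced_switch" for e in tr.events):
            break
    sw = [e for e in tr.events if e["kind"] == "induced_switch"][0]
    assert sw["time"] == pytest.approx(550.0)
    assert tr.plans[-1] == "R"


def test_intention_rejects_choice_on_blocked_side():
    cfg = cd.desk_config()
    rng = np.random.default_rng(1)
    t = make_trial(
        init=("easy", "easy"), choice="R", delay=800.0,
        change=BarrierChange(400.0, "R", "blocked"),
    )
    t.trial_class = "free_to_forced"
    with pytest.raises(ValueError, match="blocked"):
        simulate_intention(t, cfg, rng)


def _flat_intention(choice="R"):
    return IntentionTrace(trial_id=0, transitions=[0.0], plans=[choice])


def test_emit_spikes_zero_rate_is_silent():
    unit = UnitTuning(0, "PMd", 0.0, 0.0, 0.0, 0.0, 50.0)
    rng = np.random.default_rng(6)
    out = emit_spikes(_flat_intention(), [unit], rng, 0.0, 1000.0)
    assert out[0].size == 0


def test_emit_spikes_constant_rate_poisson_mean():
    unit = UnitTuning(0, "PMd", 20.0, 20.0, 20.0, 0.0, 50.0)
    rng = np.random.default_rng(7)
    counts = [
        emit_spikes(_flat_intention(), [unit], rng, 0.0, 1000.0)[0].size
        for _ in range(2000)
    ]
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - 20.0) < 4 * se + 0.05


def test_emit_spikes_matches_per_bin_poisson_distribution():
    """Thinning emission agrees in distribution with direct per-bin Poisson
    counts (KS test on total counts over a fixed window)."""
    unit = UnitTuning(0, "PMd", 10.0, 30.0, 2.0, 0.0, 40.0)
    intent = IntentionTrace(trial_id=0, transitions=[200.0], plans=["L"])
    rng = np.random.default_rng(8)
    n_rep = 1500
    thinned = np.array([
        emit_spikes(intent, [unit], rng, 0.0, 800.0)[0].size
        for _ in range(n_rep)
    ])
    # oracle: integrate the piecewise-exponential rate on a fine grid
    tg = np.linspace(0, 800.0, 8001)
    rate = np.where(
        tg < 200.0, 10.0, 30.0 + (10.0 - 30.0) * np.exp(-(tg - 200.0) / 40.0)
    )
    lam = np.trapezoid(rate, tg) / 1000.0
    direct = rng.poisson(lam, size=n_rep)
    res = sps.ks_2samp(thinned, direct)
    assert res.pvalue > 0.01


def test_ground_truth_plan_recoverable_from_rates():
    """With well-separated tuning, a naive bin-wise likelihood rule on spike
    counts recovers the planned side >= 99% of the time late in the delay."""
    cfg = cd.desk_config(
        n_trials=150, n_units=25, depth_range=(18.0, 28.0), p_vac=0.0,
        p_zero_delay=0.0,
    )
    session, truth, tuning = cd.simulate_session(cfg, seed=9)
    correct = total = 0
    for idx, trial in enumerate(session.trials):
        if trial.delay < 500.0:
            continue
        plan = truth.traces[trial.trial_id].plan_at(trial.delay - 50.0)
        if plan == "none":
            continue
        window = (trial.delay - 200.0, trial.delay)
        ll = {"L": 0.0, "R": 0.0}
        for ui, u in enumerate(tuning):
            st = session.spikes[idx][ui]
            k = np.count_nonzero((st >= window[0]) & (st < window[1]))
            for side, r in (("L", u.left_rate), ("R", u.right_rate)):
                lam = max(r, 1e-3) * 0.2
                ll[side] += k * np.log(lam) - lam
        guess = "L" if ll["L"] > ll["R"] else "R"
        total += 1
        correct += int(guess == plan)
    assert total >= 20
    assert correct / total >= 0.99


def test_vacillation_ground_truth_structure():
    cfg = cd.events_config(n_trials=200, n_units=8)
    session, truth, _ = cd.simulate_session(cfg, seed=10)
    vac_ids = truth.trial_ids_with("vacillation")
    assert len(vac_ids) >= 5
    by_id = {t.trial_id: t for t in session.trials}
    for tid in vac_ids:
        tr = truth.traces[tid]
        assert tr.n_plan_changes() == 1
        assert tr.final_plan == by_id[tid].choice
        t_vac = [e for e in tr.events if e["kind"] == "vacillation"][0]["time"]
        assert t_vac >= cfg.vac_earliest
        assert t_vac <= by_id[tid].delay
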