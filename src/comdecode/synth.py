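"""Synthetic maze-task sessions with ground-truth internal events.

The generator emulates a delayed-reach maze session: a trial schedule with
the task's timing structure (truncated-exponential delays and barrier-change
latencies), a piecewise-constant internal *intention* (motor plan) per trial,
and inhomogeneous-Poisson spike emission from choice-tuned units.  Because
the intention trace is known, downstream stages (decoder, change-of-mind
detector, RT analyses) can be scored against ground truth.

Internal events injected, with labels recorded in :class:`GroundTruth`:

- ``vacillation``: on free trials, the plan initially points to the side
  opposite the eventual choice and reverses mid-delay.
- ``induced_switch``: the plan follows a barrier change (taken encouraged
  switches, unlucky free-to-forced trials, biasing-change switches) after a
  re-planning latency.
- ``hesitation``: untaken-switch trials receive an RT penalty with *no*
  plan change.
- ``slow_plan``: zero-delay free trials form the plan late (indecision);
  the RT penalty is proportional to the lateness when coupling is on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .trials import BarrierChange, TrialRecord, other_side
from .session import SpikeSession, UnitInfo

EVENT_KINDS = ("plan_onset", "vacillation", "induced_switch", "hesitation", "slow_plan")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SessionConfig:
    """Generator settings; defaults emulate a paper-scale session."""

    n_trials: int = 1302
    n_units: int = 101
    maze_family: str = "T"

    # trial-class candidate mix (before late changes fall back to no-change)
    p_forced: float = 0.38
    p_free: float = 0.30
    p_free_to_forced: float = 0.08
    p_encouraged_switch: float = 0.12
    p_biasing: float = 0.12

    p_zero_delay: float = 0.15
    p_fail: float = 0.03

    # task timing (ms)
    delay_tau: float = 500.0
    delay_cap: float = 1000.0
    change_tau: float = 500.0
    change_cap: float = 1200.0

    # choice-probability table: P(choose L) given (difficulty_L, difficulty_R)
    p_left_table: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("easy", "easy"): 0.5,
            ("hard", "hard"): 0.5,
            ("easy", "hard"): 0.85,
            ("hard", "easy"): 0.15,
        }
    )
    p_take_switch: float = 0.35       # encouraged switch taken
    p_init_hard: float = 0.20         # biasing: initial plan on the hard side
    p_bias_switch: float = 0.17       # biasing: easy-side plan switches after change

    # internal-plan dynamics (ms)
    plan_onset_range: Tuple[float, float] = (100.0, 200.0)
    # immediate-Go trials demand a speeded initial selection; without it the
    # early decoded choice could not reflect the plan before movement
    plan_onset_zero_delay_range: Tuple[float, float] = (60.0, 120.0)
    replan_latency: float = 150.0
    replan_jitter: float = 30.0
    p_vac: float = 0.13               # vacillation prob. on eligible free trials
    vac_min_delay: float = 450.0      # vacillations only when the delay allows
    vac_earliest: float = 260.0       # and only after the plan has formed
    vac_end_margin: float = 120.0     # ... but before the analysed epoch ends

    # reaction times (ms)
    rt_base: float = 300.0
    rt_base_zero_delay: float = 350.0
    rt_sd: float = 40.0
    rt_min: float = 180.0
    hesitation_mean: float = 30.0     # exponential RT penalty, untaken switches
    indecision_scale: float = 60.0    # exponential plan-onset lateness, zero delay
    indecision_cap: float = 150.0
    indecision_coupling: float = 1.0  # RT penalty per ms of plan lateness
    p_wrong_start: float = 0.35       # indecision trials starting on the wrong side

    # unit tuning
    baseline_rate_range: Tuple[float, float] = (4.0, 12.0)
    depth_range: Tuple[float, float] = (8.0, 20.0)
    nonpref_factor: float = 0.6       # non-preferred rate = base - factor*depth
    onset_latency_range: Tuple[float, float] = (0.0, 40.0)
    ramp_tau_range: Tuple[float, float] = (30.0, 60.0)
    forced_free_gain: float = 1.0

    def class_mix(self) -> Dict[str, float]:
        mix = {
            "forced": self.p_forced,
            "free": self.p_free,
            "free_to_forced": self.p_free_to_forced,
            "encouraged_switch": self.p_encouraged_switch,
            "biasing": self.p_biasing,
        }
        for k, v in mix.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"class probability {k}={v} outside [0, 1]")
        tot = sum(mix.values())
        if not math.isclose(tot, 1.0, rel_tol=1e-6):
            raise ValueError(f"class mix must sum to 1, got {tot}")
        for p in self.p_left_table.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_left_table entries must lie in [0, 1]")
        return mix


def desk_config(**overrides) -> SessionConfig:
    """A desk-scale profile (same conditions, smaller session)."""
    base = dict(n_trials=420, n_units=36)
    base.update(overrides)
    return SessionConfig(**base)


def events_config(**overrides) -> SessionConfig:
    """Desk-scale profile weighted toward free trials with frequent injected
    vacillations, for estimating detector sensitivity/specificity.

    Tuning (SNR), timing, and per-event detectability parameters are the
    defaults; only the event *frequency* and class mix differ, to yield
    enough ground-truth events to grade recovery on one session.
    """
    base = dict(
        n_trials=420,
        n_units=36,
        p_free=0.50,
        p_forced=0.36,
        p_free_to_forced=0.04,
        p_encouraged_switch=0.05,
        p_biasing=0.05,
        p_zero_delay=0.05,
        p_vac=0.40,
    )
    base.update(overrides)
    return SessionConfig(**base)


def indecision_config(**overrides) -> SessionConfig:
    """Desk-scale profile rich in zero-delay trials, for the indecision
    regression (many immediate-choice free trials to regress RT on the
    early decoded choice).  Effect parameters are the defaults."""
    base = dict(
        n_trials=300,
        n_units=30,
        p_zero_delay=0.45,
        p_forced=0.40,
        p_free=0.44,
        p_free_to_forced=0.04,
        p_encouraged_switch=0.06,
        p_biasing=0.06,
    )
    base.update(overrides)
    return SessionConfig(**base)


def separable_config(**overrides) -> SessionConfig:
    """High-SNR, event-free profile for decoder calibration checks."""
    base = dict(
        n_trials=260,
        n_units=30,
        p_vac=0.0,
        p_fail=0.0,
        p_free_to_forced=0.0,
        p_encouraged_switch=0.0,
        p_biasing=0.0,
        p_forced=0.6,
        p_free=0.4,
        depth_range=(15.0, 25.0),
        p_wrong_start=0.0,
        indecision_scale=20.0,
        # plenty of immediate-Go trials with brisk movements, so the decode
        # window probes early delay times as well as the late plateau
        p_zero_delay=0.30,
        rt_base_zero_delay=280.0,
        rt_sd=50.0,
        rt_min=210.0,
    )
    base.update(overrides)
    return SessionConfig(**base)


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass
class IntentionTrace:
    """Piecewise-constant plan: segment k holds ``plans[k]`` from
    ``transitions[k]`` up to ``transitions[k+1]`` (or trial end); an implicit
    leading segment of no plan ("none") runs from trial start."""

    trial_id: int
    transitions: List[float]          # strictly increasing, ms
    plans: List[str]                  # "L"/"R" per segment ("none" before first)
    events: List[dict] = field(default_factory=list)  # {kind, time, ...}

    def __post_init__(self) -> None:
        if len(self.transitions) != len(self.plans):
            raise ValueError("one plan per transition required")
        if any(b <= a for a, b in zip(self.transitions, self.transitions[1:])):
            raise ValueError("transitions must be strictly increasing")

    def plan_at(self, t: float) -> str:
        idx = np.searchsorted(self.transitions, t, side="right") - 1
        return "none" if idx < 0 else self.plans[idx]

    @property
    def final_plan(self) -> str:
        return self.plans[-1] if self.plans else "none"

    def n_plan_changes(self) -> int:
        """Number of L<->R reversals (ignoring the none->side onset)."""
        return sum(1 for a, b in zip(self.plans, self.plans[1:]) if a != b)


@dataclass
class GroundTruth:
    """Per-trial intention traces and the session-level event table."""

    traces: Dict[int, IntentionTrace]

    def events(self, kind: Optional[str] = None) -> List[dict]:
        out = []
        for tid, tr in self.traces.items():
            for ev in tr.events:
                if kind is None or ev["kind"] == kind:
                    out.append({"trial_id": tid, **ev})
        return out

    def trial_ids_with(self, kind: str) -> List[int]:
        return sorted({ev["trial_id"] for ev in self.events(kind)})


@dataclass
class UnitTuning:
    unit_id: int
    array: str
    baseline_rate: float
    left_rate: float
    right_rate: float
    onset_latency: float
    ramp_tau: float
    forced_free_gain: float = 1.0

    def __post_init__(self) -> None:
        for r in (self.baseline_rate, self.left_rate, self.right_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if self.onset_latency < 0:
            raise ValueError("onset_latency must be nonnegative")


# ---------------------------------------------------------------------------
# timing distributions

def sample_truncated_exponential(
    tau: float, cap: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exponential(tau) truncated (renormalised) at ``cap``."""
    return stats.truncexpon.rvs(b=cap / tau, scale=tau, size=size, random_state=rng)


def truncated_exponential_mean(tau: float, cap: float) -> float:
    """Closed-form mean of the truncated exponential."""
    z = 1.0 - math.exp(-cap / tau)
    return tau - cap * math.exp(-cap / tau) / z


# ---------------------------------------------------------------------------
# schedule

def _sample_choice(p_left: float, rng: np.random.Generator) -> str:
    return "L" if rng.random() < p_left else "R"


def sample_trial_schedule(
    config: SessionConfig, rng: np.random.Generator
) -> List[TrialRecord]:
    """Sample the behavioral trial table (timing, configurations, choices).

    Barrier-change latencies are drawn independently of the delay; a change
    that would land at or after the Go cue never happens, and the trial
    falls back to its no-change class, as in the task.
    """
    mix = config.class_mix()
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    trials: List[TrialRecord] = []
    for tid in range(config.n_trials):
        zero = rng.random() < config.p_zero_delay
        if zero:
            delay = 0.0
            cand = "forced" if rng.random() < (
                mix["forced"] / (mix["forced"] + mix["free"])
            ) else "free"
        else:
            delay = float(
                sample_truncated_exponential(
                    config.delay_tau, config.delay_cap, 1, rng
                )[0]
            )
            cand = classes[rng.choice(len(classes), p=probs)]

        change: Optional[BarrierChange] = None
        if cand in ("free_to_forced", "encouraged_switch", "biasing"):
            t_c = float(
                sample_truncated_exponential(
                    config.change_tau, config.change_cap, 1, rng
                )[0]
            )
            if t_c >= delay:
                cand = {"free_to_forced": "free",
                        "encouraged_switch": "forced",
                        "biasing": "free_biasing_base"}[cand]
                t_c = None
        else:
            t_c = None

        if cand == "forced":
            open_side = "L" if rng.random() < 0.5 else "R"
            init = {open_side: "easy", other_side(open_side): "blocked"}
            choice = open_side
        elif cand == "free":
            init = {"L": "easy", "R": "easy"}
            choice = _sample_choice(config.p_left_table[("easy", "easy")], rng)
        elif cand == "free_biasing_base":
            hard = "L" if rng.random() < 0.5 else "R"
            init = {hard: "hard", other_side(hard): "easy"}
            choice = _sample_choice(config.p_left_table[(init["L"], init["R"])], rng)
        elif cand == "free_to_forced":
            init = {"L": "easy", "R": "easy"}
            blocked = "L" if rng.random() < 0.5 else "R"
            change = BarrierChange(time=t_c, side=blocked, new_difficulty="blocked")
            choice = other_side(blocked)
        elif cand == "encouraged_switch":
            open_side = "L" if rng.random() < 0.5 else "R"
            init = {open_side: "easy", other_side(open_side): "blocked"}
            change = BarrierChange(
                time=t_c, side=other_side(open_side), new_difficulty="easy"
            )
            taken = rng.random() < config.p_take_switch
            choice = other_side(open_side) if taken else open_side
        else:  # biasing: one side hard becomes easy
            hard = "L" if rng.random() < 0.5 else "R"
            init = {hard: "hard", other_side(hard): "easy"}
            change = BarrierChange(time=t_c, side=hard, new_difficulty="easy")
            p_hard = (
                config.p_init_hard
                + (1.0 - config.p_init_hard) * config.p_bias_switch
            )
            choice = hard if rng.random() < p_hard else other_side(hard)

        base = config.rt_base_zero_delay if zero else config.rt_base
        rt = max(config.rt_min, float(rng.normal(base, config.rt_sd)))
        success = rng.random() >= config.p_fail
        trials.append(
            TrialRecord(
                trial_id=tid,
                maze_family=config.maze_family,
                initial_difficulty=init,
                delay=delay,
                move_onset=delay + rt,
                choice=choice,
                success=success,
                barrier_change=change,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# intention

def simulate_intention(
    trial: TrialRecord, config: SessionConfig, rng: np.random.Generator
) -> IntentionTrace:
    """Simulate the internal plan for one trial.

    The trace is constructed to end at the trial's recorded choice.  May
    lengthen the trial's RT (``move_onset``) for hesitation and indecision
    events, mirroring their behavioral signatures.
    """
    if trial.delay == 0.0:
        onset = float(rng.uniform(*config.plan_onset_zero_delay_range))
    else:
        onset = float(rng.uniform(*config.plan_onset_range))
    choice = trial.choice
    cls = trial.trial_class
    events: List[dict] = []
    transitions: List[float]
    plans: List[str]

    def replan_time(t_c: float) -> float:
        return t_c + config.replan_latency + float(
            rng.uniform(-config.replan_jitter, config.replan_jitter)
        )

    if cls in ("forced", "free") and trial.delay == 0.0 and cls == "free":
        # zero-delay free choice: possible indecision (slow plan formation)
        extra = min(
            float(rng.exponential(config.indecision_scale)), config.indecision_cap
        )
        wrong = rng.random() < config.p_wrong_start
        if wrong:
            t_fix = onset + max(extra, 40.0) + 50.0
            transitions = [onset, t_fix]
            plans = [other_side(choice), choice]
            slow = t_fix - onset
        else:
            transitions = [onset + extra]
            plans = [choice]
            slow = extra
        events.append({"kind": "plan_onset", "time": transitions[0]})
        events.append({"kind": "slow_plan", "time": transitions[-1], "lateness": slow})
        trial.move_onset += config.indecision_coupling * slow
    elif cls == "free":
        eligible = trial.delay >= config.vac_min_delay
        if eligible and rng.random() < config.p_vac:
            t_vac = float(
                rng.uniform(
                    config.vac_earliest, trial.delay - config.vac_end_margin
                )
            )
            transitions = [onset, t_vac]
            plans = [other_side(choice), choice]
            events.append({"kind": "plan_onset", "time": onset})
            events.append({"kind": "vacillation", "time": t_vac})
        else:
            transitions, plans = [onset], [choice]
            events.append({"kind": "plan_onset", "time": onset})
    elif cls == "forced":
        transitions, plans = [onset], [choice]
        events.append({"kind": "plan_onset", "time": onset})
    elif cls == "free_to_forced":
        blocked = trial.barrier_change.side
        if choice == blocked:
            raise ValueError(
                f"trial {trial.trial_id}: free_to_forced choice on the blocked side"
            )
        p_left = config.p_left_table[("easy", "easy")]
        init_plan = "L" if rng.random() < p_left else "R"
        if init_plan == blocked:  # unlucky: must re-plan after the change
            t_sw = replan_time(trial.barrier_change.time)
            transitions = [onset, t_sw]
            plans = [init_plan, choice]
            events.append({"kind": "plan_onset", "time": onset})
            events.append({"kind": "induced_switch", "time": t_sw})
        else:
            transitions, plans = [onset], [choice]
            events.append({"kind": "plan_onset", "time": onset})
    elif cls == "encouraged_switch_taken":
        orig = other_side(trial.barrier_change.side)
        t_sw = replan_time(trial.barrier_change.time)
        transitions = [onset, t_sw]
        plans = [orig, choice]
        events.append({"kind": "plan_onset", "time": onset})
        events.append({"kind": "induced_switch", "time": t_sw})
    elif cls == "encouraged_switch_untaken":
        transitions, plans = [onset], [choice]
        penalty = float(rng.exponential(config.hesitation_mean))
        trial.move_onset += penalty
        events.append({"kind": "plan_onset", "time": onset})
        events.append(
            {"kind": "hesitation", "time": trial.barrier_change.time,
             "rt_penalty": penalty}
        )
    elif cls in ("biasing_likely_change", "biasing_unlikely_change"):
        hard = trial.barrier_change.side
        if cls == "biasing_likely_change":
            # chose the initially-hard side: either planned it from the start,
            # or switched to it after the change
            p_stayed = config.p_init_hard / (
                config.p_init_hard
                + (1.0 - config.p_init_hard) * config.p_bias_switch
            )
            if rng.random() < p_stayed:
                transitions, plans = [onset], [choice]
                events.append({"kind": "plan_onset", "time": onset})
            else:
                t_sw = replan_time(trial.barrier_change.time)
                transitions = [onset, t_sw]
                plans = [other_side(choice), choice]
                events.append({"kind": "plan_onset", "time": onset})
                events.append({"kind": "induced_switch", "time": t_sw})
        else:
            transitions, plans = [onset], [choice]
            events.append({"kind": "plan_onset", "time": onset})
    else:
        transitions, plans = [onset], [choice]
        events.append({"kind": "plan_onset", "time": onset})

    # drop degenerate later transitions that would land out of order
    keep_t, keep_p = [transitions[0]], [plans[0]]
    for t, p in zip(transitions[1:], plans[1:]):
        if t > keep_t[-1]:
            keep_t.append(t)
            keep_p.append(p)
        else:
            keep_p[-1] = p
    return IntentionTrace(
        trial_id=trial.trial_id, transitions=keep_t, plans=keep_p, events=events
    )


# ---------------------------------------------------------------------------
# spike emission

def sample_tuning(config: SessionConfig, rng: np.random.Generator) -> List[UnitTuning]:
    units = []
    for uid in range(config.n_units):
        base = float(rng.uniform(*config.baseline_rate_range))
        depth = float(rng.uniform(*config.depth_range))
        pref = "L" if rng.random() < 0.5 else "R"
        hi = base + depth
        lo = max(base - config.nonpref_factor * depth, 0.5)
        units.append(
            UnitTuning(
                unit_id=uid,
                array="PMd" if uid < config.n_units // 2 else "M1",
                baseline_rate=base,
                left_rate=hi if pref == "L" else lo,
                right_rate=hi if pref == "R" else lo,
                onset_latency=float(rng.uniform(*config.onset_latency_range)),
                ramp_tau=float(rng.uniform(*config.ramp_tau_range)),
                forced_free_gain=config.forced_free_gain,
            )
        )
    return units


def _rate_segments(
    intention: IntentionTrace, unit: UnitTuning, t_start: float, free_trial: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-exponential rate: (segment starts, start rates, target rates)."""
    gain = unit.forced_free_gain if free_trial else 1.0

    def target(plan: str) -> float:
        if plan == "none":
            return unit.baseline_rate
        r = unit.left_rate if plan == "L" else unit.right_rate
        return unit.baseline_rate + gain * (r - unit.baseline_rate)

    starts = [t_start]
    start_rates = [unit.baseline_rate]
    targets = [unit.baseline_rate]
    for t, plan in zip(intention.transitions, intention.plans):
        te = t + unit.onset_latency
        if te <= starts[-1]:
            targets[-1] = target(plan)
            continue
        # rate reached at te under the previous segment
        prev = targets[-1] + (start_rates[-1] - targets[-1]) * math.exp(
            -(te - starts[-1]) / unit.ramp_tau
        )
        starts.append(te)
        start_rates.append(prev)
        targets.append(target(plan))
    return np.array(starts), np.array(start_rates), np.array(targets)


def _rate_at(
    t: np.ndarray,
    starts: np.ndarray,
    start_rates: np.ndarray,
    targets: np.ndarray,
    ramp_tau: float,
) -> np.ndarray:
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    dt = t - starts[idx]
    return targets[idx] + (start_rates[idx] - targets[idx]) * np.exp(-dt / ramp_tau)


def emit_spikes(
    intention: IntentionTrace,
    tuning: Sequence[UnitTuning],
    rng: np.random.Generator,
    t_start: float,
    t_end: float,
    free_trial: bool = False,
) -> List[np.ndarray]:
    """Inhomogeneous-Poisson spike trains via thinning, one per unit."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    out = []
    for unit in tuning:
        starts, s_rates, targets = _rate_segments(
            intention, unit, t_start, free_trial
        )
        r_max = float(max(np.max(s_rates), np.max(targets)))
        if r_max < 0:
            raise ValueError("negative rate encountered")
        if r_max == 0.0:
            out.append(np.empty(0))
            continue
        lam = r_max / 1000.0  # spikes per ms
        n = rng.poisson(lam * (t_end - t_start))
        cand = np.sort(rng.uniform(t_start, t_end, size=n))
        rates = _rate_at(cand, starts, s_rates, targets, unit.ramp_tau)
        keep = rng.random(n) < rates / r_max
        st = cand[keep]
        # enforce strictly increasing times (duplicates have measure zero,
        # but guard against float ties)
        if st.size > 1:
            st = np.unique(st)
        out.append(st)
    return out


# ---------------------------------------------------------------------------
# full session

def simulate_session(
    config: Optional[SessionConfig] = None,
    seed: int = 0,
    name: str = "synthetic",
) -> Tuple[SpikeSession, GroundTruth, List[UnitTuning]]:
    """Generate a full session: schedule -> intentions -> spikes.

    Randomness flows from ``seed`` through three named substreams
    (schedule, intention, spikes), so e.g. re-drawing spikes leaves the
    behavioral schedule untouched.
    """
    config = config or SessionConfig()
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_intent, rng_spk, rng_tune = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]
    trials = sample_trial_schedule(config, rng_sched)
    tuning = sample_tuning(config, rng_tune)
    traces: Dict[int, IntentionTrace] = {}
    spikes: List[List[np.ndarray]] = []
    epoch_start = -300.0
    for trial in trials:
        tr = simulate_intention(trial, config, rng_intent)
        if tr.final_plan != trial.choice:
            raise RuntimeError("intention must end at the recorded choice")
        traces[trial.trial_id] = tr
        free_trial = trial.trial_class != "forced"
        spikes.append(
            emit_spikes(
                tr, tuning, rng_spk, epoch_start, trial.move_onset,
                free_trial=free_trial,
            )
        )
    session = SpikeSession(
        units=[UnitInfo(u.unit_id, u.array) for u in tuning],
        trials=trials,
        spikes=spikes,
        name=name,
    )
    return session, GroundTruth(traces=traces), tuning
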