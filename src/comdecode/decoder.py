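"""Time-invariant linear choice decoding of latent trajectories.

A single wide-margin linear classifier (linear-kernel SVM) is trained on
pooled (trial x eligible-bin) latent states of forced-choice trials, labeled
by the eventual choice; the *same* weights apply at every time point, so any
change in the decoded choice over a trial reflects changing neural activity
only.  The graded decoded choice is the signed distance from the separating
hyperplane, normalised by the 90th percentile of decoded values over all
trials and times of the dataset.  Sign convention: positive = rightward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from .params import PipelineParams
from .session import bins_at_or_after
from .trials import TrialRecord, select_trials

CHOICE_SIGN = {"L": -1.0, "R": 1.0}


@dataclass
class ChoiceTrace:
    """Normalised signed decoded choice over one trial's bins."""

    trial_id: int
    times: np.ndarray   # bin centers, ms
    values: np.ndarray  # signed distance / norm_constant; positive = rightward

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def last_point(self) -> float:
        """Decoded value at the final bin (ending 200 ms before movement)."""
        return float(self.values[-1])

    @property
    def predicted_choice(self) -> str:
        return "R" if self.last_point > 0 else "L"


class ChoiceDecoder(BaseEstimator):
    """Linear-SVM choice decoder applied identically at every time point.

    Parameters
    ----------
    C : float
        Soft-margin penalty (default 1.0).
    norm_quantile : float
        Quantile of decoded values used as the normalisation constant.
    norm_mode : {"abs", "signed"}
        Whether the quantile is taken over absolute or signed raw decoded
        values (default absolute: an unsigned scale factor).

    Attributes
    ----------
    w_ : (n_latents,) hyperplane normal.
    b_ : intercept.
    norm_constant_ : positive scale; decoded values are
        ``(w.x + b) / (||w|| * norm_constant_)``.
    """

    def __init__(self, C: float = 1.0, norm_quantile: float = 0.90,
                 norm_mode: str = "abs"):
        self.C = C
        self.norm_quantile = norm_quantile
        self.norm_mode = norm_mode

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ChoiceDecoder":
        """Fit on pooled latent points ``X`` with labels ``y`` in {-1, +1}."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if set(np.unique(y)) - {-1.0, 1.0, -1, 1}:
            raise ValueError("labels must be -1 (left) or +1 (right)")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        svc = SVC(kernel="linear", C=self.C)
        svc.fit(X, y)
        self.w_ = svc.coef_.ravel().copy()
        self.b_ = float(svc.intercept_[0])
        self.norm_constant_ = 1.0
        return self

    def raw_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distance from the hyperplane (unnormalised)."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.w_.size:
            raise ValueError(
                f"expected {self.w_.size}-dimensional states, got {X.shape[-1]}"
            )
        return (X @ self.w_ + self.b_) / np.linalg.norm(self.w_)

    def set_norm_constant(self, all_states: np.ndarray) -> float:
        """Set the normalisation from decoded values of all session points."""
        vals = self.raw_values(all_states)
        if self.norm_mode == "abs":
            vals = np.abs(vals)
        elif self.norm_mode != "signed":
            raise ValueError("norm_mode must be 'abs' or 'signed'")
        c = float(np.quantile(vals, self.norm_quantile))
        if c <= 0:
            c = 1.0
        self.norm_constant_ = c
        return c

    def values(self, X: np.ndarray) -> np.ndarray:
        """Normalised signed decoded choice for latent states."""
        return self.raw_values(X) / self.norm_constant_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.values(X) > 0, 1.0, -1.0)

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "w": self.w_.tolist(),
            "b": self.b_,
            "norm_constant": self.norm_constant_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChoiceDecoder":
        model = cls(**d["params"])
        model.w_ = np.asarray(d["w"], dtype=float)
        model.b_ = float(d["b"])
        model.norm_constant_ = float(d["norm_constant"])
        return model


# ---------------------------------------------------------------------------
# session-level training and decoding

def _pool_training_points(
    latents: Dict[int, np.ndarray],
    times: Dict[int, np.ndarray],
    trials: Sequence[TrialRecord],
    train_ids: Sequence[int],
    params: PipelineParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack eligible bins (left edge >= train_start) of the training trials."""
    by_id = {t.trial_id: t for t in trials}
    Xs, ys, tid_of_point = [], [], []
    for tid in train_ids:
        mask = bins_at_or_after(times[tid], params.train_start, params)
        if not mask.any():
            continue
        Xs.append(latents[tid][mask])
        sign = CHOICE_SIGN[by_id[tid].choice]
        ys.append(np.full(mask.sum(), sign))
        tid_of_point.append(np.full(mask.sum(), tid))
    if not Xs:
        raise ValueError("no eligible training points")
    return np.concatenate(Xs), np.concatenate(ys), np.concatenate(tid_of_point)


def training_trial_ids(
    trials: Sequence[TrialRecord], params: PipelineParams, trial_class: str = "forced"
) -> List[int]:
    """The decoder training set: successful trials of the given class with
    delay >= min_delay and no barrier change."""
    return select_trials(
        trials,
        success=True,
        trial_class=trial_class,
        min_delay=params.min_delay,
        no_barrier_change=True,
    )


def train_decoder(
    latents: Dict[int, np.ndarray],
    times: Dict[int, np.ndarray],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
    trial_class: str = "forced",
) -> ChoiceDecoder:
    """Train the session decoder on pooled forced-choice latent points.

    The normalisation constant comes from decoded values of *all* session
    trials (every bin of every trial with latents), not just the training
    class.
    """
    params = params or PipelineParams()
    train_ids = training_trial_ids(trials, params, trial_class)
    if len(train_ids) < 2:
        raise ValueError(f"fewer than 2 {trial_class} training trials")
    X, y, _ = _pool_training_points(latents, times, trials, train_ids, params)
    model = ChoiceDecoder(norm_quantile=params.norm_quantile)
    model.fit(X, y)
    all_states = np.concatenate([latents[tid] for tid in latents])
    model.set_norm_constant(all_states)
    return model


def decode_trace(
    model: ChoiceDecoder,
    latents_one_trial: np.ndarray,
    times_one_trial: np.ndarray,
    trial_id: int,
) -> ChoiceTrace:
    """Decode one trial's trajectory into a normalised choice trace."""
    return ChoiceTrace(
        trial_id=trial_id,
        times=np.asarray(times_one_trial, dtype=float),
        values=model.values(np.asarray(latents_one_trial, dtype=float)),
    )


def decode_session(
    model: ChoiceDecoder,
    latents: Dict[int, np.ndarray],
    times: Dict[int, np.ndarray],
) -> Dict[int, ChoiceTrace]:
    return {
        tid: decode_trace(model, latents[tid], times[tid], tid) for tid in latents
    }


@dataclass
class LooResult:
    """Leave-one-out cross-validated decoding of the training class."""

    traces: Dict[int, ChoiceTrace]          # held-out decodes
    fold_models: Dict[int, ChoiceDecoder]   # fold = held-out trial id
    fold_train_ids: Dict[int, List[int]]    # training trials of each fold
    accuracy: float                         # final-point accuracy
    skipped: List[int]                      # folds skipped (single class)


def loo_cross_validate(
    latents: Dict[int, np.ndarray],
    times: Dict[int, np.ndarray],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
    trial_class: str = "forced",
    labels: Optional[Dict[int, str]] = None,
) -> LooResult:
    """Decode each eligible trial with a model trained without it.

    Each fold retains its own decoder (weights + norm constant from all
    session points) and its training-trial ids, so downstream event
    detection can use that fold's class-conditional distributions.
    ``labels`` optionally overrides trial choices (e.g. for label-shuffle
    controls).
    """
    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    train_ids = training_trial_ids(trials, params, trial_class)
    if len(train_ids) < 3:
        raise ValueError("need at least 3 eligible trials for leave-one-out")
    if labels is not None:
        lab = dict(labels)
    else:
        lab = {tid: by_id[tid].choice for tid in train_ids}

    # pooled eligible points for all training trials, tagged by trial
    Xs, tid_tags = [], []
    for tid in train_ids:
        mask = bins_at_or_after(times[tid], params.train_start, params)
        Xs.append(latents[tid][mask])
        tid_tags.append(np.full(mask.sum(), tid))
    Xpool = np.concatenate(Xs)
    tags = np.concatenate(tid_tags)
    ypool = np.array([CHOICE_SIGN[lab[tid]] for tid in tags], dtype=float)
    all_states = np.concatenate([latents[tid] for tid in latents])

    traces: Dict[int, ChoiceTrace] = {}
    fold_models: Dict[int, ChoiceDecoder] = {}
    fold_train: Dict[int, List[int]] = {}
    skipped: List[int] = []
    n_correct = 0
    n_scored = 0
    for tid in train_ids:
        keep = tags != tid
        if len(np.unique(ypool[keep])) < 2:
            skipped.append(tid)
            continue
        model = ChoiceDecoder(norm_quantile=params.norm_quantile)
        model.fit(Xpool[keep], ypool[keep])
        model.set_norm_constant(all_states)
        trace = decode_trace(model, latents[tid], times[tid], tid)
        traces[tid] = trace
        fold_models[tid] = model
        fold_train[tid] = [t for t in train_ids if t != tid]
        n_scored += 1
        if np.sign(trace.last_point) == CHOICE_SIGN[lab[tid]]:
            n_correct += 1
    accuracy = n_correct / n_scored if n_scored else float("nan")
    return LooResult(
        traces=traces,
        fold_models=fold_models,
        fold_train_ids=fold_train,
        accuracy=accuracy,
        skipped=skipped,
    )


def performance_vs_time(
    traces: Dict[int, ChoiceTrace],
    trials: Sequence[TrialRecord],
    params: Optional[PipelineParams] = None,
) -> Dict[float, Tuple[int, float]]:
    """Final-point accuracy per 60 ms bin of the last decoded time point.

    Returns ``{bin_start_ms: (n_trials, accuracy)}``; bins with no trials
    are absent (missing, not zero).
    """
    params = params or PipelineParams()
    by_id = {t.trial_id: t for t in trials}
    bins: Dict[float, List[bool]] = {}
    for tid, trace in traces.items():
        t_last = float(trace.times[-1])
        b = math.floor(t_last / params.perf_bin) * params.perf_bin
        correct = np.sign(trace.last_point) == CHOICE_SIGN[by_id[tid].choice]
        bins.setdefault(b, []).append(bool(correct))
    return {
        b: (len(v), float(np.mean(v))) for b, v in sorted(bins.items())
    }


def performance_pvalue(
    n_correct: int,
    n_trials: int,
    prevalence: float = 0.5,
    reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo p-value that chance decoding performs >= observed.

    Each simulated run picks every trial's decoded choice at random
    according to the class prevalence; the p-value is the add-one-corrected
    fraction of runs with at least ``n_correct`` matches.
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError("need 0 <= n_correct <= n_trials")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_r = int(round(prevalence * n_trials))  # trials whose true label is "right"
    n_l = n_trials - n_r
    n_ge = 0
    chunk = 2_000_000
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        sim = rng.binomial(n_r, prevalence, size=m)
        if n_l:
            sim = sim + rng.binomial(n_l, 1.0 - prevalence, size=m)
        n_ge += int(np.count_nonzero(sim >= n_correct))
        done += m
    return (n_ge + 1) / (reps + 1)
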