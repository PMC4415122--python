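"""Spike-session container, spike binning, and fixture I/O.

A :class:`SpikeSession` bundles a trial table with per-trial, per-unit spike
times (ms relative to maze onset) and unit metadata (array label, PMd or M1).
Sessions round-trip losslessly through a newline-delimited JSON fixture
format: the first line is a header describing the units, each subsequent
line one trial with its spike trains.

Binning convention: half-open bins ``[epoch_start + k*w, epoch_start +
(k+1)*w)`` anchored at ``epoch_start``; the per-trial epoch ends at the last
*full* bin before ``move_onset - epoch_end_offset`` (trailing partial bin
dropped), so the summed counts equal the number of in-window spikes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import PipelineParams
from .trials import TrialRecord

_FORMAT_NAME = "comdecode-session"
_FORMAT_VERSION = 1


@dataclass
class UnitInfo:
    unit_id: int
    array: str  # "PMd" or "M1"

    def to_dict(self) -> dict:
        return {"unit_id": self.unit_id, "array": self.array}


@dataclass
class SpikeSession:
    """Units, per-trial spike trains, and the trial table for one session."""

    units: List[UnitInfo]
    trials: List[TrialRecord]
    spikes: List[List[np.ndarray]]  # [trial][unit] -> sorted spike times, ms
    name: str = "session"

    def __post_init__(self) -> None:
        if not (1 <= len(self.units) <= 1000):
            raise ValueError("unit count must lie in [1, 1000]")
        if len(self.spikes) != len(self.trials):
            raise ValueError("one spike-train list required per trial")
        for ti, trains in enumerate(self.spikes):
            if len(trains) != len(self.units):
                raise ValueError(f"trial {ti}: expected {len(self.units)} trains")
            for ui, st in enumerate(trains):
                st = np.asarray(st, dtype=float)
                if st.ndim != 1:
                    raise ValueError("spike trains must be 1-D")
                if st.size > 1 and np.any(np.diff(st) <= 0):
                    raise ValueError(
                        f"trial {ti} unit {ui}: spike times must be strictly sorted"
                    )
                self.spikes[ti][ui] = st

    @property
    def n_units(self) -> int:
        return len(self.units)

    def trial_by_id(self, trial_id: int) -> TrialRecord:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(f"no trial with id {trial_id}")

    def index_of(self, trial_id: int) -> int:
        for i, t in enumerate(self.trials):
            if t.trial_id == trial_id:
                return i
        raise KeyError(f"no trial with id {trial_id}")

    def subset_units(self, array: str) -> "SpikeSession":
        """Restrict the session to units from one array (PMd or M1)."""
        keep = [i for i, u in enumerate(self.units) if u.array == array]
        if not keep:
            raise ValueError(f"no units on array {array!r}")
        return SpikeSession(
            units=[self.units[i] for i in keep],
            trials=self.trials,
            spikes=[[trains[i] for i in keep] for trains in self.spikes],
            name=f"{self.name}-{array}",
        )


def n_epoch_bins(move_onset: float, params: PipelineParams) -> int:
    """Number of full bins between epoch_start and move_onset - offset."""
    span = move_onset - params.epoch_end_offset - params.epoch_start
    return int(math.floor(span / params.bin_width + 1e-9))


def bin_centers(n_bins: int, params: PipelineParams) -> np.ndarray:
    w = params.bin_width
    return params.epoch_start + w * (np.arange(n_bins) + 0.5)


def bins_at_or_after(times: np.ndarray, t_min: float, params: PipelineParams) -> np.ndarray:
    """Mask of bins whose *left edge* is at/after ``t_min``.

    ``times`` are bin centers; a bin counts as "at time >= t" when its full
    extent lies at/after t.
    """
    return (times - params.bin_width / 2.0) >= t_min - 1e-9


def bin_index_containing(t: float, params: PipelineParams) -> int:
    """Index of the bin whose half-open extent contains time ``t``."""
    return int(math.floor((t - params.epoch_start) / params.bin_width + 1e-9))


def bin_spikes(
    spikes: Sequence[float],
    epoch: Tuple[float, float],
    bin_width: float,
) -> np.ndarray:
    """Count spikes in half-open bins over ``[epoch[0], epoch[1])``.

    Spikes outside the epoch are ignored and a trailing partial bin is
    dropped. Input must be sorted ascending.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    start, end = epoch
    if end - start < bin_width:
        raise ValueError("epoch must cover at least one bin")
    st = np.asarray(spikes, dtype=float)
    if st.size > 1 and np.any(np.diff(st) <= 0):
        raise ValueError("spike times must be strictly sorted ascending")
    n_bins = int(math.floor((end - start) / bin_width + 1e-9))
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(st, bins=edges)
    return counts.astype(np.int64)


def bin_session(
    session: SpikeSession,
    params: Optional[PipelineParams] = None,
    trial_ids: Optional[Sequence[int]] = None,
) -> Tuple[List[np.ndarray], List[np.ndarray], List[int]]:
    """Bin every requested trial of a session.

    Returns ``(counts, times, trial_ids)`` where ``counts[i]`` is a
    (n_bins_i, n_units) integer array, ``times[i]`` the matching bin centers.
    Trials too short to contain a single full bin are skipped.
    """
    params = params or PipelineParams()
    if trial_ids is None:
        trial_ids = [t.trial_id for t in session.trials]
    counts_list, times_list, kept = [], [], []
    for tid in trial_ids:
        idx = session.index_of(tid)
        trial = session.trials[idx]
        n_bins = n_epoch_bins(trial.move_onset, params)
        if n_bins < 1:
            continue
        epoch = (
            params.epoch_start,
            params.epoch_start + n_bins * params.bin_width,
        )
        mat = np.stack(
            [
                bin_spikes(session.spikes[idx][ui], epoch, params.bin_width)
                for ui in range(session.n_units)
            ],
            axis=1,
        )
        counts_list.append(mat)
        times_list.append(bin_centers(n_bins, params))
        kept.append(tid)
    return counts_list, times_list, kept


def save_session(session: SpikeSession, path) -> None:
    """Write a session to the newline-delimited JSON fixture format."""
    with open(path, "w") as fh:
        header = {
            "format": _FORMAT_NAME,
            "version": _FORMAT_VERSION,
            "name": session.name,
            "time_unit": "ms",
            "units": [u.to_dict() for u in session.units],
        }
        fh.write(json.dumps(header) + "\n")
        for trial, trains in zip(session.trials, session.spikes):
            rec = trial.to_dict()
            rec["spikes"] = [st.tolist() for st in trains]
            fh.write(json.dumps(rec) + "\n")


def load_session(path) -> SpikeSession:
    """Read a session fixture; malformed records raise with their line."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty fixture")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: line 1: malformed header ({e})") from e
    if header.get("format") != _FORMAT_NAME:
        raise ValueError(f"{path}: line 1: not a {_FORMAT_NAME} fixture")
    units = [UnitInfo(int(u["unit_id"]), u["array"]) for u in header["units"]]
    trials, spikes = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            trial = TrialRecord.from_dict(rec)
            trains = [np.asarray(st, dtype=float) for st in rec["spikes"]]
        except (json.JSONDecodeError, KeyError, ValueError) as e:
            raise ValueError(f"{path}: line {lineno}: malformed trial record ({e})") from e
        for ui, st in enumerate(trains):
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError(
                    f"{path}: line {lineno}: unit {ui} spike times not sorted"
                )
        trials.append(trial)
        spikes.append(trains)
    return SpikeSession(
        units=units, trials=trials, spikes=spikes, name=header.get("name", "session")
    )


def trials_to_dataframe(trials: Sequence[TrialRecord]):
    """TrialRecord table as a pandas DataFrame (for CSV export)."""
    import pandas as pd

    rows = []
    for t in trials:
        d = t.to_dict()
        bc = d.pop("barrier_change")
        d["initial_difficulty_L"] = d["initial_difficulty"]["L"]
        d["initial_difficulty_R"] = d.pop("initial_difficulty")["R"]
        d["barrier_change_time"] = None if bc is None else bc["time"]
        d["barrier_change_side"] = None if bc is None else bc["side"]
        d["barrier_change_new"] = None if bc is None else bc["new_difficulty"]
        d["rt"] = t.rt
        rows.append(d)
    return pd.DataFrame(rows)
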