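"""Shared fixtures: synthetic sessions run through the full pipeline once
per test session and reused across test modules.

Problem sizes are desk-scale (a few hundred trials, ~30 units, 8 latents,
a capped EM iteration budget); the generator's tuning and timing parameters
are the package defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import comdecode as cd
from comdecode.params import PipelineParams
from comdecode.pipeline import decode_pipeline, detect_all_events, score_against_ground_truth


def desk_params(**overrides) -> PipelineParams:
    base = dict(n_latents=8, gpfa_max_iter=12, gpfa_tol=1e-6)
    base.update(overrides)
    return PipelineParams(**base)


@pytest.fixture(scope="session")
def events_run():
    """Free-heavy session with frequent injected vacillations, decoded and
    scored against ground truth (detector recovery conditions)."""
    cfg = cd.events_config(n_trials=300, n_units=30)
    session, truth, tuning = cd.simulate_session(cfg, seed=3)
    ds = decode_pipeline(session, desk_params())
    calls = detect_all_events(ds)
    score = score_against_ground_truth(calls, truth)
    return dict(
        config=cfg, session=session, truth=truth, tuning=tuning,
        ds=ds, calls=calls, score=score,
    )


@pytest.fixture(scope="session")
def separable_run():
    """High-SNR event-free session with the plan-formation latency pinned
    at 150 ms (decoder-calibration conditions)."""
    cfg = cd.separable_config(plan_onset_range=(150.0, 150.0))
    session, truth, tuning = cd.simulate_session(cfg, seed=4)
    ds = decode_pipeline(session, desk_params())
    return dict(config=cfg, session=session, truth=truth, ds=ds)


@pytest.fixture(scope="session")
def desk_run():
    """Default-profile desk-scale session (indecision coupling on)."""
    cfg = cd.desk_config(n_trials=320, n_units=30)
    session, truth, tuning = cd.simulate_session(cfg, seed=5)
    ds = decode_pipeline(session, desk_params())
    calls = detect_all_events(ds)
    return dict(config=cfg, session=session, truth=truth, ds=ds, calls=calls)


@pytest.fixture(scope="session")
def indecision_run():
    """Zero-delay-rich session with the indecision RT coupling on."""
    cfg = cd.indecision_config()
    session, truth, tuning = cd.simulate_session(cfg, seed=7)
    ds = decode_pipeline(session, desk_params(), run_loo=False)
    return dict(config=cfg, session=session, truth=truth, ds=ds)


@pytest.fixture(scope="session")
def nocoupling_run():
    """Zero-delay-rich session with the indecision coupling switched off
    (null dataset: RT independent of the early decoded choice)."""
    cfg = cd.indecision_config(indecision_coupling=0.0, p_wrong_start=0.0)
    session, truth, tuning = cd.simulate_session(cfg, seed=6)
    ds = decode_pipeline(session, desk_params(), run_loo=False)
    return dict(config=cfg, session=session, truth=truth, ds=ds)
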