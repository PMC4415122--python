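"""Pipeline-wide numeric constants.

All times are milliseconds relative to maze onset (targets + barriers appear
at t = 0); the Go cue occurs at ``delay`` and movement onset at
``delay + rt``.  Every analysis stage reads its constants from a single
:class:`PipelineParams` instance so that one convention (half-open 20 ms bins
anchored at ``epoch_start``) propagates everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass
class PipelineParams:
    """Numeric constants shared across the decoding pipeline.

    Parameters
    ----------
    bin_width : float
        Spike-count bin width in ms (default 20).
    n_latents : int
        GPFA latent dimensionality (default 12).
    epoch_start : float
        Start of the analysed epoch, ms before maze onset (default -300).
    epoch_end_offset : float
        The epoch ends this many ms *before* movement onset (default 200),
        excluding movement-epoch activity.
    train_start : float
        Decoder training uses bins starting at/after this time (default 80),
        so training activity at least partially reflects a choice.
    min_delay : float
        Minimum delay (maze onset to Go) for decoder-based analyses (300).
    psth_min_delay : float
        Minimum delay for PSTH-based analyses (350).
    com_window_start : float
        Change-of-mind criteria consider bins at/after this time (160);
        approximate plan-formation time rounded up to the bin grid.
    lr_threshold : float
        Likelihood-ratio threshold for "strongly left/right" (10).
    pool_from : float
        Forced-choice class-conditional fits pool all bins at/after this
        time into one bin (600).
    norm_quantile : float
        Decoded values are normalised by this quantile of all decoded
        values for the dataset (0.90).
    perf_bin : float
        Width of delay bins for the performance-vs-time curve (60).
    baseline_window : tuple
        Window defining the mean baseline neural state (-300, -40).
    com_rate_window : float
        Width of the firing-rate window centred on a crossing (200).
    psth_sd : float
        Gaussian smoothing SD for PSTHs, ms (30).
    corr_window : tuple
        Epoch for the forced/free similarity analysis (-200, +300).
    snr_min : float
        SNR gate for the similarity analysis (4).
    indecision_probe : float
        Decoded choice is probed this many ms after maze onset for the
        indecision regression (100).
    indecision_min_rt : float
        Minimum RT for trials entering the indecision regression (300).
    near_go_margin : float
        A barrier change counts as "near Go" if it occurs no more than this
        many ms before the Go cue (50).
    delay_tau, delay_cap : float
        Truncated-exponential delay distribution (tau 500, cap 1000).
    change_tau, change_cap : float
        Truncated-exponential barrier-change latency (tau 500, cap 1200).
    mc_reps : int
        Monte-Carlo repetitions for the decoder p-value (default 10**7;
        lower it for desk-scale runs).
    """

    bin_width: float = 20.0
    n_latents: int = 12
    epoch_start: float = -300.0
    epoch_end_offset: float = 200.0
    train_start: float = 80.0
    min_delay: float = 300.0
    psth_min_delay: float = 350.0
    com_window_start: float = 160.0
    lr_threshold: float = 10.0
    pool_from: float = 600.0
    norm_quantile: float = 0.90
    perf_bin: float = 60.0
    baseline_window: Tuple[float, float] = (-300.0, -40.0)
    com_rate_window: float = 200.0
    psth_sd: float = 30.0
    corr_window: Tuple[float, float] = (-200.0, 300.0)
    snr_min: float = 4.0
    indecision_probe: float = 100.0
    indecision_min_rt: float = 300.0
    near_go_margin: float = 50.0
    delay_tau: float = 500.0
    delay_cap: float = 1000.0
    change_tau: float = 500.0
    change_cap: float = 1200.0
    mc_reps: int = 10_000_000
    # GPFA fitting controls
    gpfa_tol: float = 1e-8
    gpfa_max_iter: int = 500
    sqrt_transform: bool = True
    sigma_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not (0.0 < self.norm_quantile < 1.0):
            raise ValueError(
                f"norm_quantile must lie in (0, 1), got {self.norm_quantile}"
            )
        if not (self.epoch_start < self.train_start < self.pool_from):
            raise ValueError("require epoch_start < train_start < pool_from")
        if self.com_window_start % self.bin_width != 0:
            raise ValueError("com_window_start must be a multiple of bin_width")
        for name in ("baseline_window", "corr_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have start < end")
        if self.n_latents < 1:
            raise ValueError("n_latents must be >= 1")
        if self.mc_reps < 1:
            raise ValueError("mc_reps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        d = dict(d)
        for name in ("baseline_window", "corr_window"):
            if name in d and isinstance(d[name], list):
                d[name] = tuple(d[name])
        return cls(**d)
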