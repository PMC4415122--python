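# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `comdecode`.  All times are in milliseconds
relative to maze onset (targets and barriers appear at t = 0); the Go cue
occurs at `delay` and movement onset at `delay + rt`.

## Time grid and binning

Spike counts use half-open, left-closed bins of width 20 ms anchored at the
epoch start (−300 ms): bin *k* covers `[−300 + 20k, −300 + 20(k+1))`.  Each
trial's epoch ends at the last *full* bin before `move_onset − 200` ms, so
summed counts always equal the number of in-window spikes and movement-epoch
activity is excluded.  A bin's reported time is its center; a bin counts as
"at time ≥ t" when its left edge is ≥ t.  Windows stated below (80 ms
training start, 160 ms change-of-mind start, 600 ms pooling start) are all
multiples of the bin width, so no bin straddles a boundary.  Movement-onset
times are not aligned to the grid; the trailing partial bin is simply
dropped.

## Latent model (GPFA)

Square-rooted counts (variance-stabilising for Poisson data; on by default,
off via `sqrt_transform=False`) follow a linear-Gaussian observation model
`y_t = C x_t + d + ε_t`, `ε_t ~ N(0, R)` with diagonal `R`, and each latent
dimension an independent zero-mean GP over the trial's bins with a
squared-exponential kernel `K_i(t,s) = (1−σ_n) exp(−(t−s)²/2τ_i²) + σ_n δ`,
`σ_n = 10⁻³` fixed.  Defaults: 12 latents, 20 ms bins.

Fitting is EM on all successful trials of a session pooled together.  The
E-step is the exact Gaussian posterior per trial; trials of the same length
share every expensive matrix factor, which is what makes variable-length
trials cheap (no padding; per-length kernel matrices).  The M-step updates
`C, d, R` in closed form; each timescale τ_i is updated by bounded scalar
maximisation of its expected complete-data log-likelihood term and the
update is accepted only if it improves that term — a generalised M-step, so
the data log-likelihood is non-decreasing at every iteration (asserted in
tests to 10⁻⁸ relative).  Initialisation is a static factor analysis
(random initialisation available for stress tests); convergence is a
relative log-likelihood change below `gpfa_tol` (10⁻⁸ by default) or
`gpfa_max_iter` iterations.  `R` is floored at 10⁻⁶.

`C` is deliberately not orthonormalised for decoding: the decoder is linear,
so any invertible linear change of latent basis is absorbed into its
weights and cannot affect decoded signs or ratios of decoded values.

Dimensionality is a configuration constant, not auto-selected.  Downstream
conclusions on synthetic data were checked to be insensitive to the
square-root transform; both settings are exposed.

## Decoder

A linear-kernel SVM (soft margin C = 1, features not re-standardised — the
latents already share a scale) is trained on pooled (trial × bin) latent
states of successful forced-choice trials with delay ≥ 300 ms and no
barrier change, using bins from 80 ms after maze onset to the epoch end;
each eligible bin of each trial contributes one equally weighted point,
labeled by the eventual choice.  The decoded choice at any time is
`(w·x_t + b) / (‖w‖ · c)` with `c` the 90th percentile of **absolute** raw
decoded values over *all* trials and time points of the dataset (taking the
percentile over signed values is available via `norm_mode="signed"`; the
wording of the normalisation leaves this open and an unsigned scale factor
is the conservative reading).  Sign convention: positive = rightward
(asserted everywhere; the choice of sign is arbitrary and documented).

The same `(w, b)` applies at every bin — the decoder is time-invariant by
construction, and a permutation test on the bins of a trial confirms the
decoded values permute identically.  "Final point" means the last full bin
ending at or before `move_onset − 200` ms.

Leave-one-out cross-validation refits the SVM without the held-out trial;
each fold retains its own weights, normalisation constant, and training
trial ids so that event detection on cross-validated trials can use that
fold's class-conditional distributions only.  The decoder-performance
p-value is a Monte-Carlo simulation assigning each trial a random decoded
choice at the class prevalence (default 10⁷ repetitions; the CLI profile
uses 10⁵), with the add-one correction `(k+1)/(N+1)`.

## Change-of-mind detector

Per-bin Gaussians `(μ, σ)` are fit to forced-left and forced-right decoded
values on the decoder grid from 80 ms up to 600 ms; all bins at/after
600 ms pool into one late bin.  SDs use the unbiased (n−1) estimator and
are floored at σ_floor = 10⁻³ normalised units (degenerate bins would
otherwise produce infinite likelihood ratios); a bin with fewer than two
values per class inherits its nearest earlier bin with a warning.

A trial with delay ≥ 300 ms is an event iff, over bins at/after 160 ms:
(1) the decode changes sign at least once; (2) some point is ≥ 10× as
likely under the left as under the right forced distribution; (3) some
point is ≥ 10× as likely under the right as under the left.  The three
criteria may be satisfied at *different* time points (read literally: the
decode must swing from strongly-left to strongly-right or vice versa, not
necessarily instantaneously).  Exactly-zero values inherit the previous
bin's sign; a sign change is timed at the midpoint of the flanking bin
centers; `last_crossing` reports the final such change.  Bins before 80 ms
have no class-conditional model and cannot satisfy criteria 2–3.

Raising the likelihood threshold can only shrink the event set (tested);
negating all traces while swapping the class models flips directions but
not event flags (tested).

## Synthetic generator

The generator emulates the task, not the circuit: its purpose is to carry
known internal events through realistic spiking so recovery can be scored.

**Schedule.** Delays are truncated-exponential (τ = 500 ms, cap 1000 ms);
barrier-change latencies likewise (cap 1200 ms), drawn independently of
the delay — a change that would land after the Go cue never happens and the
trial falls back to its no-change class.  A configurable fraction of trials
(default 0.15) has zero delay (Go at maze onset).  Trial classes (forced,
free, free-to-forced, encouraged switch, biasing change) are drawn from a
configurable mix; choices follow a configurable table of
P(left | barrier configuration), with switch-type choices (take the newly
opened target; switch to the newly eased target) governed by their own
probabilities.  A small fraction of trials (default 3%) is marked
unsuccessful and excluded from every analysis.

**Intention.** Each trial has a piecewise-constant plan: none → side at a
plan-formation latency drawn uniformly from 100–200 ms, then at most one
reversal.  Injected events: *vacillations* (free trials, probability 0.13
when the delay ≥ 450 ms allows one) start on the side opposite the eventual
choice and reverse at a uniform time between 260 ms and `delay − 120` ms —
mid-delay, so both plans are expressed inside the analysed epoch;
*induced switches* re-plan 150 ± 30 ms after a barrier change (taken
switches, unlucky free-to-forced trials, and the switched fraction of
biasing-change trials); *hesitations* (untaken switches) add an
exponential RT penalty (mean 30 ms, hence a ≈ 21 ms median shift) with no
plan change; *slow plans* (zero-delay free trials) delay plan formation by
an exponential lateness (scale 60 ms, cap 150 ms), optionally starting on
the wrong side (probability 0.35), with the RT penalised proportionally
(`indecision_coupling`, default 1; set 0 for null datasets).  Zero-delay
trials draw their base plan-formation latency from 60–120 ms: an
immediate-Go condition demands a speeded initial selection, and without it
the early decoded choice could not reflect the plan before movement.

**Spikes.** Each unit has a baseline rate (4–12 spikes/s), a preferred-side
rate (baseline + 8–20 spikes/s), a non-preferred rate, a response latency
(0–40 ms) and an exponential ramp time constant (30–60 ms); rates follow
the plan with those dynamics and spikes are emitted by thinning an
inhomogeneous Poisson process.  The rate model is an invention — the
simplest form that reproduces delay-period selectivity phenomenology — and
is validated against a direct per-bin Poisson sampler in distribution.
Half the units are labeled PMd, half M1, enabling split-array analyses.
Movement-epoch activity is not modeled (decoding stops 200 ms before
movement onset).  RT = base (300 ms; 350 ms for zero-delay trials) +
Gaussian noise (SD 40 ms) + event penalties.

All randomness flows from a single seed through named substreams
(schedule / intention / spikes / tuning): a fixed seed reproduces a session
bitwise, and changing what one substream consumes leaves the others'
outputs unchanged.

**Profiles.** The default configuration is paper-scale (1302 trials, 101
units).  Tests and the acceptance script use desk-scale profiles (200–420
trials, 25–36 units, 8 latents, EM capped at 12 iterations) chosen so the
full battery runs in minutes; two purpose-built profiles adjust *sampling*
only, never per-event detectability: `events_config` weights the class mix
toward free trials and raises the vacillation frequency so one session
yields enough ground-truth events to estimate sensitivity, and
`indecision_config` raises the zero-delay fraction so the RT regression has
enough immediate-choice trials.  `separable_config` is a high-SNR,
event-free profile for decoder-calibration checks.

**What the generator does not emulate.** No correlated noise beyond the
shared plan signal, no LFP, no kinematics, no non-stationarity across a
session, and vacillation is limited to one reversal per trial.  Passing
recovery tests therefore shows the pipeline is correct and calibrated under
these idealised conditions; it does not certify performance on real
recordings, where noise correlations and drift can degrade both decoding
and detection.

## Statistics

- PSTHs: single-trial rates smoothed with a 30 ms-SD Gaussian whose kernel
  is renormalised inside the evaluation window (mass-conserving at edges);
  mean ± SEM across trials (SEM computed after per-trial smoothing); trials
  require delay ≥ 350 ms.
- Forced/free similarity: per unit, Pearson r between concatenated
  forced-[L,R] and free-[L,R] mean vectors over −200..+300 ms; SNR =
  range of the concatenated signal vector / largest SEM, gate at 4; sign
  test across included units.  Possible change-of-mind trials (any decoded
  point ≥ 160 ms disagreeing with the eventual choice) are excluded from
  free-trial averages.
- Tuning/preference: a unit is "tuned" by a two-sided Wilcoxon rank-sum on
  delay-epoch (80 ms → Go) mean rates, forced-L vs forced-R, α = 0.05, no
  multiplicity correction; "maintained" if the free-trial preference sign
  matches.  The tuning test itself is a documented package choice.
- Baseline distance: mean latent state over −300..−40 ms across all
  successful trials; Euclidean distances in the full latent space for
  baseline bins, the two bins flanking each event's last crossing, and all
  bins ≥ 160 ms.
- Crossing-window rates: per unit, rate in the 200 ms window centred on an
  event trial's last crossing vs the mean rate of non-event free-left and
  free-right trials over the same absolute window (clipped to each trial's
  epoch with a warning); categories lower / between / higher with ties
  counted as *between* (conservative toward the null); two-proportion
  Z-test on lower vs higher counts.
- RT: two-sided Mann–Whitney U, exact when both groups have ≤ 20
  observations, otherwise the tie-corrected normal approximation; medians
  reported.
- Indecision regression: zero-delay free trials with RT ≥ 300 ms; OLS of
  RT on the decoded value at the bin containing +100 ms, sign-aligned so
  that agreement with the eventual reach is positive; 95% CI from the
  standard linear-model formula.  Trials too short to contain the probe bin
  are skipped.
- Split-array agreement: separate GPFA + decoder fits per array (latent
  count reduced with a warning if an array has fewer units); per-trial
  agreement is the fraction of bins ≥ 160 ms with equal decoded sign,
  averaged over successful delay ≥ 300 trials, reported for all trials and
  free-choice trials.
- Event frequencies: per trial class, Wilson score intervals at z = 1
  (equivalent to ±1 s.e.m. coverage) and χ² 2×2 contingency tests without
  continuity correction for the stated contrasts (forced vs free, untaken
  vs taken switches, unlikely vs likely biasing changes).  A 2×2 table with
  an empty margin returns p = 1 rather than an error.

## Known limitations

- GPFA learns one kernel family (squared-exponential); no mixture of
  timescales per latent.
- The detector reports at most the last crossing; multi-event trials are
  summarised, not segmented.
- Pre-maze decoded values are unconstrained by the model (no baseline
  symmetry is enforced); the detector window starting at 160 ms excludes
  them by design.
- The LOO SVM refit is exact but O(n_trials) fits per session; sessions of
  thousands of trials may warrant warm-started solvers.
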