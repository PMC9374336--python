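# Methods notes

## Scope and data model

`catrans` analyzes single-neuron calcium activity from 10 Hz miniscope
recordings in two paradigms: an acute-injection session (10-min
pre-injection baseline, 0–10 min *initial* and 50–60 min *decay*
post-injection windows) and a two-chamber place-preference session in which
the animal freely alternates between a saline-paired and a cocaine-paired
chamber. Input is either ΔF/noise traces or pre-extracted transient times;
everything downstream works on event trains plus, for the trace-based
tests, the traces themselves.

Conventions: times in seconds, rates in events/min, all windows and
episodes half-open `[t0, t1)` so boundary events are counted exactly once.

## Transient detection

Calcium dynamics are modelled as AR(1): `c_t = γ c_{t−1} + s_t` with
`s_t ≥ 0` the underlying activity. Deconvolution solves

    min ½‖y − c‖² + λ Σ s_t,   s ≥ 0

by the online active-set / pool-adjacent-violators scheme: frames are
scanned once; each frame opens a pool whose fitted value is the weighted
regression of the pool's samples on the decaying kernel, and adjacent pools
merge whenever the earlier pool's extrapolation exceeds the later pool's
start (i.e. the `s ≥ 0` constraint would be violated). The ℓ1 term is
folded into the regression target analytically (`ỹ_t = y_t − λ(1−γ)`,
last frame `y_T − λ`). Because the AR(1) impulse response is nonnegative,
`s ≥ 0` already implies `c ≥ 0`, and only a leading run of pools can come
out negative; that run's constrained optimum is zero and is clamped. The
solver is exact: on ≤ 50-frame instances its objective agrees with an
independent NNLS reformulation to ~1e−15 (tested to 1e−8).

* `γ` defaults to `exp(−1/(τ·rate))` with τ = 1 s at 10 Hz, a GCaMP6m-scale
  decay. Pass a different `ar_coefficient` or use `DeconvParams.from_tau`.
* `λ` defaults to 0; sparsification is done by the event-calling threshold,
  which keeps the solver an exact inverse on clean data.
* Events are called at local maxima of `s` above `k × σ̂`, where `σ̂` is the
  median absolute deviation of the trace's first difference scaled by
  `1/(√2·0.6745)` (the first difference of an AR(1)-plus-white-noise trace
  is noise-dominated away from onsets). Candidates closer than
  `min_separation` (2 frames) are merged keeping the larger.
* `k` defaults to 2. With unit-amplitude transients the deconvolved
  activity at an event is ≈ 1 while its noise floor is ≈ 1.34 × the trace
  noise sd; `k = 2` puts the threshold roughly midway at realistic noise
  levels (0.2–0.3 ΔF/noise) and yields recall/precision ≥ 0.95 on
  synthetic sessions, where `k = 3` already misses ~13% of unit events at
  noise 0.2. Users with larger transients or quieter data can raise `k`.

The exact definition of vendor "ΔF over noise" normalization is
proprietary; the MAD-based estimate is a documented stand-in, and all
thresholds are expressed in multiples of it.

## Injection-response classification

**Permutation (transients) method.** The statistic is the actual transient
change Δ = count(post) − count(pre) over two equal-duration windows. The
null hypothesis is that transient timing is exchangeable across the two
windows at fixed interval structure: events of both windows are pooled on a
concatenated pseudo-timeline (the decay window is mapped to abut the
baseline window, preserving each window's internal interval structure),
the N−1 intertransient intervals are permuted uniformly (default 10,000
replicates), event times are rebuilt from the first event's original
offset, and Δ* is recorded per replicate. Labels use strict inequalities
against the 1st/99th percentiles of Δ* (linear interpolation between order
statistics). Design choices, each an explicit switch or documented
behavior:

* The leading gap before the first event is not permuted (only intervals
  are shuffled); reconstruction is anchored at the first event's offset.
* Events reconstructed past the timeline end are dropped — possible only
  through floating-point rounding, since interval permutation conserves
  total span.
* Neurons with fewer than `min_events = 3` pooled events (fewer than two
  intervals) are nonclassifiable and reported nonresponsive: a 2-event
  train has a single interval and no shuffle distribution.
* With all intervals equal the null is degenerate (every Δ* equals Δ) and
  the neuron is necessarily nonresponsive — the correct behavior for
  metronomic firing.

Calibration: on 500 simulated unmodulated Poisson neurons (6/min) the
responsive fraction is ≈ 2%, matching the nominal two 1% tails.

**Trace method.** The two windows are z-scored *jointly*, averaged into ten
1-min bins per window, and the ten paired differences are tested with the
exact two-sided Wilcoxon signed-rank test; direction comes from the sign of
the mean paired difference. Z-scoring each window separately would force
both window means to zero and make the paired test nearly degenerate; the
per-window mode is still available (`zscore_mode="per_window"`) for
comparison with analyses that normalized windows independently. Note the
exact n = 10 signed-rank test is conservative at α = 0.05: its attainable
p-values are multiples of 1/512, so the realized type-I rate sits below the
nominal level.

**Population summaries** report percentages to one decimal and the
inhibited/excited fold change to one decimal (undefined when no neuron is
excited), and the persistence table counts initial-phase responders that
keep their label in the decay phase.

## Context-encoding (CACE) classification

Occupancy is segmented into maximal constant-chamber runs; runs longer than
`min_dwell = 5 s` become episodes (runs at or below the threshold still
count as visits for entry detection). Per-episode transient frequency is
events/duration (reported per minute); the trace variant uses the episode
mean of the ΔF/noise trace. Saline- versus cocaine-chamber values are
compared with a two-sided Mann-Whitney U test:

* exact, by enumerating all C(n₁+n₂, n₁) splits of the observed midranks,
  for combined episode counts ≤ 20 — this conditions on ties exactly,
  which matters because low-count episodes tie often (many zeros);
* tie-corrected normal approximation (no continuity correction) otherwise.

Neurons with fewer than 3 episodes in either chamber are labelled
`nonclassifiable` (the U test is essentially powerless below that).
Two-sidedness is a deliberate choice — the direction of modulation is an
outcome, not an assumption.

Peri-entry alignment: entries are all transitions into the target chamber
regardless of flanking dwell (a `min_flanking_dwell` switch restores a
stricter definition); entries whose ±5-s window leaves the session are
dropped; rates are binned at 1 s and averaged over entries, then neurons.

Behavioral CPP score = post-conditioning − pre-conditioning time in the
cocaine-paired chamber (seconds), with the cocaine chamber assigned as the
less-preferred chamber at baseline; animals with a baseline minority-side
preference below 25% are flagged `excluded`. The label-swap symmetry test
(saline↔cocaine relabeling negates the score) applies with
`assign_by_preference=False`, since preference-based assignment is itself
label-invariant.

## Synthetic sessions

The generator reproduces the statistical structure the analysis assumes,
with known per-neuron ground truth:

* transients: piecewise-homogeneous Poisson trains; rate = baseline before
  the injection (or in the saline chamber) and baseline × multiplier after
  (or in the cocaine chamber). Defaults mirror the modulation asymmetry
  seen after acute cocaine: 15% excited ×2.5, 30% inhibited ×0.4
  (injection) and 5% excited ×2.5, 17% inhibited ×0.3 (place preference).
* baseline rates: log-normal across neurons (median 4 events/min,
  σ_log = 0.5). Event-rate statistics for this neuron population are not
  published; these are simulator conventions chosen to be GCaMP6m-scale
  and heterogeneous, because identical rates make permutation nulls
  unrealistically uniform. Set `baseline_sigma_log = 0` for fixed rates
  (used in the calibration/recovery studies at 6/min).
* traces: unit-amplitude exponential kernels `exp(−t/τ)` (τ = 1 s) at the
  nearest frame plus white Gaussian noise (sd 0.3 ΔF/noise by default).
* occupancy: alternating chambers with shifted-exponential dwells
  (floor 2 s, mean 20 s), so stays straddle the 5-s episode threshold.
* randomness: one seed spawns a behavior stream plus one substream per
  neuron, so enlarging the population never perturbs the behavior
  trajectory or earlier neurons' trains.

What the generator does **not** emulate: pixel-level movies, motion
artifacts, calcium nonlinearity/saturation, amplitude variability, bursty
(non-Poisson) firing, and behavioral state beyond chamber identity.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the model's own assumptions, not robustness to
every property of real recordings.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script use 300–1000
neurons and 1000 shuffles; these sizes put Monte-Carlo error well inside
the asserted bands while keeping the full suite fast. Percentiles use
linear interpolation; rank tests use midranks; exact-test p-values count
outcomes at least as extreme with a 1e−12 guard against float rounding;
zero paired differences are dropped (Wilcoxon convention), and an all-zero
difference vector is reported nonresponsive rather than an error.

## Known limitations

* The permutation null conditions on the observed interval multiset; very
  low-rate neurons (a handful of events) have coarse, conservative nulls.
* Suppression of already-quiet neurons is intrinsically hard to detect;
  recovered inhibited fractions under-estimate truth when baseline rates
  are low (see the worked example in the README).
* The decay-phase comparison concatenates non-adjacent windows; the
  junction interval spans the gap and is treated like any other interval.
* No multiple-testing correction is applied across neurons, matching the
  source analysis convention; population fractions should be read against
  the ≈2% (permutation) / ≤5% (rank tests) false-positive floors.
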