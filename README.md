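# catrans

Calcium-transient analysis for single-cell miniscope recordings of drug
injection and place-conditioning experiments.

In deep-brain calcium imaging, each neuron is reduced to a ΔF/noise trace
sampled at 10 Hz and, after deconvolution, to a train of discrete calcium
transients. Two recurring analysis questions follow: *did an acute drug
injection change this neuron's activity?* and *does this neuron fire
differently in a drug-paired context than in a neutral one?* `catrans`
implements both analyses as a tested, reusable pipeline — plus a synthetic
session generator with known ground truth, so every stage runs and can be
validated without any recording data.

The package is aimed at systems-neuroscience users who already have
extracted traces or event times (e.g. from CNMF-E-style cell extraction)
and want transparent, reproducible statistics downstream.

## Methods at a glance

**Transient detection.** Traces are deconvolved under AR(1) calcium
dynamics, c_t = γ·c_{t−1} + s_t, by solving

> min ½‖y − c‖² + λ‖s‖₁  subject to s ≥ 0

with an online active-set (pool-adjacent-violators) scheme, then transients
are called at local maxima of s exceeding k× an MAD-based noise estimate.

**Injection responses.** For two equal 10-min windows around the injection,
the *actual transient change* is Δ = N_post − N_pre. The null distribution
is built by pooling both windows' events, permuting the intertransient
intervals (10,000 shuffles), and recomputing Δ* for each shuffled train. A
neuron is *excited* if Δ exceeds the 99th percentile of Δ*, *inhibited* if
it falls below the 1st percentile. A complementary trace-based test
z-scores the two windows, averages them into ten 1-min bins, and applies
the exact two-sided Wilcoxon signed-rank test to the paired bin means.

**Context-encoding (CACE) neurons.** Place-preference occupancy is
segmented into chamber-staying episodes (> 5 s). Per-episode transient
frequencies (or per-episode mean trace values) in the cocaine-paired versus
saline-paired chamber are compared with a two-sided Mann-Whitney U test
(exact by enumeration for small episode counts, tie-corrected normal
approximation otherwise). Event rates are also aligned to chamber entries
(−5 to +5 s, 1-s bins), and the behavioral CPP score is the
post-conditioning minus pre-conditioning time in the cocaine-paired
chamber, assigned as the initially less-preferred chamber.

## Worked example

Simulate an injection session with known response structure (15% of
neurons excited ×2.5, 30% inhibited ×0.4 after the injection) and recover
it with the permutation classifier:

```python
from catrans import (SynthSessionParams, simulate_injection_session,
                     classify_population, summarize_population, PermutationConfig)

params = SynthSessionParams(n_neurons=200, seed=1)   # 15% excited, 30% inhibited
_, trains, truth = simulate_injection_session(params, include_traces=False)
cfg = PermutationConfig(n_permutations=2000, seed=2)
results = classify_population(trains, (-600.0, 0.0), (0.0, 600.0), cfg)
for k, v in summarize_population(results).items():
    print(f"{k}: {v}")
```

```
n_total: 200
n_excited: 27
n_inhibited: 38
n_nonresponsive: 135
pct_excited: 13.5
pct_inhibited: 19.0
pct_nonresponsive: 67.5
fold_inhibited_over_excited: 1.4
```

The classifier recovers the excited fraction almost exactly (13.5% vs the
generated 15%); the inhibited fraction is lower than the generated 30%
because baseline rates here are heterogeneous (log-normal, median
4 events/min) and suppression of an already-quiet neuron removes too few
events to clear the 1st-percentile threshold — the same asymmetry in
statistical power that real recordings face. At a fixed 6 events/min
baseline the recovered fractions land within about two points of truth
(see `scripts/acceptance.py`).

A command-line interface mirrors the library:

```bash
catrans simulate-injection --n-neurons 100 --seed 1 --out session/
catrans classify-injection --events session/events.csv --n-perm 10000 \
        --seed 2 --out labels.csv
catrans simulate-cpp --n-neurons 100 --seed 3 --out cpp/
catrans cpp-score --pre cpp/occupancy.csv --post cpp/occupancy.csv
```

## Layout

- `src/catrans/synth.py` — synthetic injection / place-preference sessions
- `src/catrans/events.py` — z-scoring, AR(1) deconvolution, event calling
- `src/catrans/injection.py` — permutation and trace classifiers, summaries
- `src/catrans/context.py` — episodes, CACE classification, peri-entry, CPP score
- `src/catrans/ranktests.py` — exact signed-rank and Mann-Whitney tests
- `src/catrans/pipeline.py` — configuration, orchestration, reports
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
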