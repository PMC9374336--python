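"""Injection-response classification: transient-change arithmetic, the
interval-shuffling null, both classifiers, and population summaries."""

from itertools import permutations

import numpy as np
import pytest

from catrans import (
    EXCITED,
    INHIBITED,
    NONRESPONSIVE,
    ClassificationResult,
    NotClassifiableError,
    ParameterError,
    PermutationConfig,
    SynthSessionParams,
    TraceTestConfig,
    actual_transient_change,
    classify_by_traces,
    classify_by_transients,
    classify_population,
    group_frequency_change,
    overlap_analysis,
    shuffled_change_distribution,
    simulate_injection_session,
    summarize_population,
)
from catrans.injection import _pseudo_timeline

from conftest import make_trace, make_train

PRE = (-600.0, 0.0)
POST = (0.0, 600.0)


def enumerate_shuffled_changes(train, pre, post):
    """Exhaustive interval-shuffle null: one change per interval ordering."""
    events, dur_pre, total = _pseudo_timeline(train, pre, post)
    intervals = np.diff(events)
    anchor = events[0]
    out = []
    for perm in permutations(intervals):
        t = anchor + np.concatenate([[0.0], np.cumsum(perm)])
        t = t[t < total]
        out.append(int(np.sum(t >= dur_pre) - np.sum(t < dur_pre)))
    return np.asarray(out)


class TestActualChange:
    @pytest.mark.parametrize(
        "pre_times,post_times,expected",
        [
            (np.linspace(-500, -50, 5), np.linspace(50, 500, 5), 0),
            (np.linspace(-500, -100, 2), np.linspace(50, 550, 9), 7),
            (np.linspace(-500, -100, 9), np.linspace(50, 550, 2), -7),
        ],
    )
    def test_count_difference(self, pre_times, post_times, expected):
        train = make_train(np.concatenate([pre_times, post_times]), span=(-600, 600))
        assert actual_transient_change(train, PRE, POST) == expected

    def test_antisymmetric_under_window_swap(self):
        train = make_train(np.concatenate([np.linspace(-500, -100, 2),
                                           np.linspace(50, 550, 9)]), span=(-600, 600))
        assert actual_transient_change(train, POST, PRE) == -7

    def test_unequal_durations_rejected(self):
        train = make_train([1.0], span=(-600, 600))
        with pytest.raises(ParameterError):
            actual_transient_change(train, (-600, 0), (0, 300))


class TestShuffledDistribution:
    def test_periodic_train_degenerate_null(self):
        """Equal intertransient intervals: every shuffled change equals the
        actual change."""
        train = make_train(np.arange(-570.0, 600.0, 60.0), span=(-600, 600))
        delta = actual_transient_change(train, PRE, POST)
        null = shuffled_change_distribution(
            train, PRE, POST, PermutationConfig(n_permutations=500, seed=1)
        )
        assert np.all(null == delta)

    @pytest.mark.parametrize("seed", range(3))
    def test_monte_carlo_matches_exhaustive_enumeration(self, seed):
        """5 events with distinct intervals: the Monte-Carlo null matches the
        exhaustive 4!-ordering distribution within 2% total variation."""
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(-590, 590, 5))
        train = make_train(times, span=(-600, 600))
        mc = shuffled_change_distribution(
            train, PRE, POST, PermutationConfig(n_permutations=10_000, seed=seed + 10)
        )
        exact = enumerate_shuffled_changes(train, PRE, POST)
        values = np.union1d(mc, exact)
        p_mc = np.array([(mc == v).mean() for v in values])
        p_ex = np.array([(exact == v).mean() for v in values])
        assert 0.5 * np.abs(p_mc - p_ex).sum() <= 0.02

    def test_deterministic_given_seed(self):
        train = make_train(np.sort(np.random.default_rng(2).uniform(-590, 590, 40)),
                           span=(-600, 600))
        cfg = PermutationConfig(n_permutations=1000, seed=77)
        a = shuffled_change_distribution(train, PRE, POST, cfg)
        b = shuffled_change_distribution(train, PRE, POST, cfg)
        np.testing.assert_array_equal(a, b)

    def test_too_few_events_signalled(self):
        train = make_train([-100.0, 100.0], span=(-600, 600))
        with pytest.raises(NotClassifiableError):
            shuffled_change_distribution(train, PRE, POST, PermutationConfig())


class TestClassifyByTransients:
    def test_identical_pre_post_pattern_nonresponsive(self):
        pre_ev = np.linspace(-550, -50, 6)
        train = make_train(np.concatenate([pre_ev, pre_ev + 600.0]), span=(-600, 600))
        res = classify_by_transients(train, PRE, POST,
                                     PermutationConfig(n_permutations=1000, seed=3))
        assert res.statistic == 0.0
        assert res.label == NONRESPONSIVE

    def test_strong_suppression_labelled_inhibited(self):
        """Baseline 8/min suppressed to x0.3 after injection: expected change
        is about -56 counts, far outside any shuffled percentile."""
        rng = np.random.default_rng(4)
        pre_ev = np.sort(rng.uniform(-600, 0, rng.poisson(80)))
        post_ev = np.sort(rng.uniform(0, 600, rng.poisson(24)))
        train = make_train(np.concatenate([pre_ev, post_ev]), span=(-600, 600))
        res = classify_by_transients(train, PRE, POST,
                                     PermutationConfig(n_permutations=2000, seed=5))
        assert res.label == INHIBITED
        assert res.statistic < res.null_low

    def test_sparse_train_nonresponsive(self):
        train = make_train([-100.0, 100.0], span=(-600, 600))
        res = classify_by_transients(train, PRE, POST, PermutationConfig())
        assert res.label == NONRESPONSIVE

    def test_antisymmetry_under_window_swap(self):
        """Swapping pre and post maps excited to inhibited and vice versa on
        clearly modulated neurons."""
        p = SynthSessionParams(n_neurons=60, baseline_rate=6.0, baseline_sigma_log=0.0,
                               frac_excited=0.25, frac_inhibited=0.25, seed=6)
        _, trains, truth = simulate_injection_session(p, include_traces=False)
        cfg = PermutationConfig(n_permutations=1000, seed=7)
        fwd = classify_population(trains, PRE, POST, cfg)
        rev = classify_population(trains, POST, PRE, cfg)
        swap = {EXCITED: INHIBITED, INHIBITED: EXCITED, NONRESPONSIVE: NONRESPONSIVE}
        mismatch = sum(r.label != swap[f.label] for f, r in zip(fwd, rev))
        assert mismatch <= 3  # borderline neurons may flip either side of a percentile


class TestClassifyByTraces:
    def test_identical_windows_nonresponsive(self, rng):
        seg = rng.normal(0, 1, 6000)
        trace = make_trace(np.concatenate([seg, seg]), start_time=-600.0)
        res = classify_by_traces(trace, PRE, POST, TraceTestConfig())
        assert res.label == NONRESPONSIVE

    def test_uniform_step_increase_detected_with_exact_p(self, rng):
        """Post window shifted +1 everywhere: all ten paired bin differences
        positive, exact signed-rank p = 2/2^10 < 0.05, excited."""
        vals = np.concatenate([rng.normal(0, 0.1, 6000), rng.normal(1, 0.1, 6000)])
        trace = make_trace(vals, start_time=-600.0)
        res = classify_by_traces(trace, PRE, POST, TraceTestConfig())
        assert res.label == EXCITED
        assert res.p_value == pytest.approx(2.0 / 1024.0, abs=1e-15)

    def test_decrease_labelled_inhibited(self, rng):
        vals = np.concatenate([rng.normal(1, 0.1, 6000), rng.normal(0, 0.1, 6000)])
        trace = make_trace(vals, start_time=-600.0)
        res = classify_by_traces(trace, PRE, POST, TraceTestConfig())
        assert res.label == INHIBITED

    def test_per_window_mode_runs(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 6000), rng.normal(1, 0.1, 6000)])
        trace = make_trace(vals, start_time=-600.0)
        res = classify_by_traces(trace, PRE, POST, TraceTestConfig(zscore_mode="per_window"))
        assert res.label in (EXCITED, INHIBITED, NONRESPONSIVE)


def _results(n_exc, n_inh, n_total, method="transients"):
    labels = [EXCITED] * n_exc + [INHIBITED] * n_inh + [NONRESPONSIVE] * (n_total - n_exc - n_inh)
    return [
        ClassificationResult(neuron_id=f"n{i:04d}", label=lab, method=method)
        for i, lab in enumerate(labels)
    ]


class TestSummaries:
    def test_population_percentages_and_fold_change(self):
        s = summarize_population(_results(49, 117, 356))
        assert (s["pct_excited"], s["pct_inhibited"]) == (13.8, 32.9)
        assert s["fold_inhibited_over_excited"] == 2.4

    def test_small_fractions(self):
        s = summarize_population(_results(24, 31, 361))
        assert (s["pct_excited"], s["pct_inhibited"]) == (6.6, 8.6)

    def test_no_responders_fold_undefined(self):
        s = summarize_population(_results(0, 0, 10))
        assert (s["pct_excited"], s["pct_inhibited"]) == (0.0, 0.0)
        assert s["fold_inhibited_over_excited"] is None

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            summarize_population([])

    def test_overlap_persistence_percentages(self):
        initial = _results(49, 117, 356)
        decay = _results(29, 0, 356)
        # make exactly 30 of the 117 initial-inhibited persist
        for r in decay[49: 49 + 30]:
            r.label = INHIBITED
        table = overlap_analysis(initial, decay)
        assert table[EXCITED] == {"n_initial": 49, "n_persisting": 29, "pct_persisting": 59.2}
        assert table[INHIBITED]["n_persisting"] == 30
        assert table[INHIBITED]["pct_persisting"] == 25.6

    def test_overlap_empty_direction(self):
        table = overlap_analysis(_results(0, 0, 5), _results(0, 0, 5))
        assert table[EXCITED]["pct_persisting"] is None

    def test_overlap_id_mismatch_rejected(self):
        a = _results(1, 1, 3)
        b = _results(1, 1, 4)
        with pytest.raises(ParameterError):
            overlap_analysis(a, b)


class TestGroupFrequencyChange:
    def test_single_neuron_group_means_and_sem(self):
        train = make_train(
            np.concatenate([np.linspace(-590, -10, 12), np.linspace(10, 590, 6)]),
            span=(-600, 600),
        )
        labels = [ClassificationResult(neuron_id="n0", label=EXCITED, method="transients")]
        df = group_frequency_change([train], labels, PRE, POST)
        pre_row = df[(df.group == EXCITED) & (df.window == "pre")].iloc[0]
        post_row = df[(df.group == EXCITED) & (df.window == "post")].iloc[0]
        assert pre_row.mean_freq_per_min == pytest.approx(1.2)
        assert post_row.mean_freq_per_min == pytest.approx(0.6)
        assert pre_row["sem"] == 0.0

    def test_suppressed_group_post_mean_near_half(self):
        """Simulated inhibited group at multiplier 0.5: post mean within
        3 sem of half the pre mean."""
        p = SynthSessionParams(n_neurons=120, baseline_rate=6.0, baseline_sigma_log=0.0,
                               frac_excited=0.0, frac_inhibited=1.0,
                               multiplier_inhibited=0.5, seed=8)
        _, trains, truth = simulate_injection_session(p, include_traces=False)
        labels = [ClassificationResult(neuron_id=t.neuron_id, label=INHIBITED,
                                       method="transients") for t in trains]
        df = group_frequency_change(trains, labels, PRE, POST)
        pre_row = df[(df.group == INHIBITED) & (df.window == "pre")].iloc[0]
        post_row = df[(df.group == INHIBITED) & (df.window == "post")].iloc[0]
        expected = 0.5 * pre_row.mean_freq_per_min
        tol = 3 * max(post_row["sem"], pre_row["sem"])
        assert abs(post_row.mean_freq_per_min - expected) < tol

    def test_identical_windows_identical_means(self):
        train = make_train(np.linspace(-590, -10, 12), span=(-600, 600))
        labels = [ClassificationResult(neuron_id="n0", label=EXCITED, method="transients")]
        df = group_frequency_change([train], labels, PRE, PRE)
        means = df[df.group == EXCITED].mean_freq_per_min.to_numpy()
        assert means[0] == means[1]
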