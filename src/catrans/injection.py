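"""Injection-response classification.

Two complementary per-neuron tests of whether an intraperitoneal injection
(saline or cocaine) changed a neuron's activity between two equal-duration
10-min windows:

* **transients** — a point-process permutation test.  The actual transient
  change is the post-window event count minus the pre-window count.  The
  null is built by pooling the events of both windows on one concatenated
  pseudo-timeline, shuffling the intertransient intervals uniformly at
  random (10,000 replicates by default), and recomputing the count change
  of each shuffled train.  A neuron is excited when its actual change
  exceeds the 99th percentile of the shuffled changes and inhibited when it
  falls below the 1st percentile (strict inequalities, linearly
  interpolated percentiles).

* **traces** — the two windows of the dF/noise trace are z-scored jointly,
  averaged into ten 1-min bins per window, and the paired bin means are
  compared with the exact two-sided Wilcoxon signed-rank test; direction is
  the sign of the mean paired difference.

Population summaries report the excited/inhibited percentages, the
inhibited-to-excited fold change, and the persistence of initial-phase
labels into the decay phase.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import count_events, transient_frequency
from .ranktests import wilcoxon_signed_rank
from .types import (
    EXCITED,
    INHIBITED,
    NONRESPONSIVE,
    ClassificationResult,
    DegenerateInputError,
    EventTrain,
    FluorescenceTrace,
    NotClassifiableError,
    ParameterError,
    PermutationConfig,
    TraceTestConfig,
)

__all__ = [
    "actual_transient_change",
    "shuffled_change_distribution",
    "classify_by_transients",
    "classify_by_traces",
    "classify_population",
    "summarize_population",
    "overlap_analysis",
    "group_frequency_change",
]

logger = logging.getLogger(__name__)

Interval = Tuple[float, float]


def _check_equal_durations(pre: Interval, post: Interval) -> Tuple[float, float]:
    dur_pre = pre[1] - pre[0]
    dur_post = post[1] - post[0]
    if dur_pre <= 0 or dur_post <= 0:
        raise ParameterError("windows must have positive duration")
    if abs(dur_pre - dur_post) > 1e-9:
        raise ParameterError(
            f"pre ({dur_pre} s) and post ({dur_post} s) windows must have equal duration"
        )
    return dur_pre, dur_post


def actual_transient_change(train: EventTrain, pre: Interval, post: Interval) -> int:
    """Post-window event count minus pre-window event count."""
    _check_equal_durations(pre, post)
    return count_events(train, post) - count_events(train, pre)


def _pseudo_timeline(train: EventTrain, pre: Interval, post: Interval) -> Tuple[np.ndarray, float, float]:
    """Map the events of both windows onto one concatenated timeline.

    The pre window maps to [0, dur_pre) and the post window to
    [dur_pre, dur_pre + dur_post), abutting even when the real windows are
    separated (decay-phase comparisons); this preserves the interval
    structure within each window while giving the shuffle one contiguous
    support.
    """
    dur_pre, dur_post = _check_equal_durations(pre, post)
    t = train.event_times
    ev_pre = t[(t >= pre[0]) & (t < pre[1])] - pre[0]
    ev_post = t[(t >= post[0]) & (t < post[1])] - post[0] + dur_pre
    return np.concatenate([ev_pre, ev_post]), dur_pre, dur_pre + dur_post


def shuffled_change_distribution(
    train: EventTrain,
    pre: Interval,
    post: Interval,
    cfg: PermutationConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Null distribution of the transient change under interval shuffling.

    Each replicate permutes the intertransient intervals of the pooled
    events, rebuilds a train anchored at the first original event's offset,
    drops any event reconstructed past the timeline end (possible only
    through floating-point rounding, since interval permutation conserves
    the total span), and records shuffled-post minus shuffled-pre counts.
    """
    events, dur_pre, total = _pseudo_timeline(train, pre, post)
    n = events.size
    if n < cfg.min_events:
        raise NotClassifiableError(
            f"neuron {train.neuron_id}: {n} events < min_events={cfg.min_events}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    intervals = np.diff(events)
    anchor = events[0]
    B = cfg.n_permutations
    perms = rng.permuted(np.tile(intervals, (B, 1)), axis=1)
    times = np.empty((B, n))
    times[:, 0] = anchor
    np.cumsum(perms, axis=1, out=times[:, 1:])
    times[:, 1:] += anchor
    pre_counts = (times < dur_pre).sum(axis=1)
    post_counts = ((times >= dur_pre) & (times < total)).sum(axis=1)
    return (post_counts - pre_counts).astype(np.int64)


def classify_by_transients(
    train: EventTrain,
    pre: Interval,
    post: Interval,
    cfg: PermutationConfig,
    rng: Optional[np.random.Generator] = None,
    phase: Optional[str] = None,
) -> ClassificationResult:
    """Label a neuron by the interval-shuffling permutation test."""
    delta = actual_transient_change(train, pre, post)
    try:
        null = shuffled_change_distribution(train, pre, post, cfg, rng=rng)
    except NotClassifiableError:
        return ClassificationResult(
            neuron_id=train.neuron_id, label=NONRESPONSIVE, method="transients",
            statistic=float(delta), phase=phase,
        )
    lo, hi = np.percentile(null, [cfg.lower_percentile, cfg.upper_percentile])
    if delta > hi:
        label = EXCITED
    elif delta < lo:
        label = INHIBITED
    else:
        label = NONRESPONSIVE
    return ClassificationResult(
        neuron_id=train.neuron_id, label=label, method="transients",
        statistic=float(delta), null_low=float(lo), null_high=float(hi), phase=phase,
    )


def _bin_means(segment: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0, segment.size, n_bins + 1).round().astype(int)
    return np.array([segment[a:b].mean() for a, b in zip(edges, edges[1:])])


def classify_by_traces(
    trace: FluorescenceTrace,
    pre: Interval,
    post: Interval,
    cfg: TraceTestConfig,
    phase: Optional[str] = None,
) -> ClassificationResult:
    """Label a neuron by the binned z-scored trace comparison.

    The pre and post segments are z-scored jointly by default
    (``cfg.zscore_mode``): z-scoring each window separately forces both
    window means to zero and degenerates the paired test.
    """
    seg_pre = trace.segment(*pre)
    seg_post = trace.segment(*post)

    def _z(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError(f"trace {trace.neuron_id}: zero variance")
        return (x - mu) / sd

    if cfg.zscore_mode == "joint":
        both = np.concatenate([seg_pre, seg_post])
        mu, sd = float(both.mean()), float(both.std(ddof=0))
        seg_pre = _z(seg_pre, mu, sd)
        seg_post = _z(seg_post, mu, sd)
    else:
        seg_pre = _z(seg_pre, float(seg_pre.mean()), float(seg_pre.std(ddof=0)))
        seg_post = _z(seg_post, float(seg_post.mean()), float(seg_post.std(ddof=0)))

    bins_pre = _bin_means(seg_pre, cfg.n_bins)
    bins_post = _bin_means(seg_post, cfg.n_bins)
    diffs = bins_post - bins_pre
    try:
        res = wilcoxon_signed_rank(diffs)
    except DegenerateInputError:
        return ClassificationResult(
            neuron_id=trace.neuron_id, label=NONRESPONSIVE, method="traces",
            statistic=0.0, p_value=1.0, phase=phase,
        )
    if res.p_value < cfg.alpha:
        label = EXCITED if diffs.mean() > 0 else INHIBITED
    else:
        label = NONRESPONSIVE
    return ClassificationResult(
        neuron_id=trace.neuron_id, label=label, method="traces",
        statistic=float(res.statistic), p_value=float(res.p_value), phase=phase,
    )


def classify_population(
    trains: Sequence[EventTrain],
    pre: Interval,
    post: Interval,
    cfg: PermutationConfig,
    phase: Optional[str] = None,
) -> List[ClassificationResult]:
    """Permutation-classify every neuron with independent seed substreams.

    Substreams are spawned from ``cfg.seed`` in neuron order, so results do
    not depend on how the caller iterates or parallelizes.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(len(trains))
    out = []
    for train, child in zip(trains, children):
        out.append(
            classify_by_transients(
                train, pre, post, cfg, rng=np.random.default_rng(child), phase=phase
            )
        )
    return out


def _label_counts(results: Iterable[ClassificationResult]) -> Dict[str, int]:
    counts = {EXCITED: 0, INHIBITED: 0, NONRESPONSIVE: 0}
    total = 0
    for r in results:
        total += 1
        counts[r.label if r.label in counts else NONRESPONSIVE] += 1
    counts["total"] = total
    return counts


def summarize_population(results: Sequence[ClassificationResult]) -> Dict[str, object]:
    """Population fractions and the inhibited/excited fold change.

    Percentages are reported to one decimal place; the fold change is the
    inhibited count over the excited count (one decimal), undefined (None)
    when no neuron is excited.
    """
    results = list(results)
    if not results:
        raise ParameterError("summarize_population: empty result set")
    c = _label_counts(results)
    total = c["total"]
    pct = lambda k: round(100.0 * c[k] / total, 1)
    fold = round(c[INHIBITED] / c[EXCITED], 1) if c[EXCITED] > 0 else None
    return {
        "n_total": total,
        "n_excited": c[EXCITED],
        "n_inhibited": c[INHIBITED],
        "n_nonresponsive": c[NONRESPONSIVE],
        "pct_excited": pct(EXCITED),
        "pct_inhibited": pct(INHIBITED),
        "pct_nonresponsive": pct(NONRESPONSIVE),
        "fold_inhibited_over_excited": fold,
    }


def overlap_analysis(
    initial: Sequence[ClassificationResult], decay: Sequence[ClassificationResult]
) -> Dict[str, Dict[str, object]]:
    """Persistence of initial-phase labels into the decay phase.

    For each direction, the count and percentage of initial-phase
    excited/inhibited neurons that carry the same label in the decay phase.
    """
    init_by_id = {r.neuron_id: r for r in initial}
    decay_by_id = {r.neuron_id: r for r in decay}
    if set(init_by_id) != set(decay_by_id):
        raise ParameterError("overlap_analysis: neuron ids differ between phases")
    table: Dict[str, Dict[str, object]] = {}
    for direction in (EXCITED, INHIBITED):
        ids = [nid for nid, r in init_by_id.items() if r.label == direction]
        persist = [nid for nid in ids if decay_by_id[nid].label == direction]
        table[direction] = {
            "n_initial": len(ids),
            "n_persisting": len(persist),
            "pct_persisting": round(100.0 * len(persist) / len(ids), 1) if ids else None,
        }
    return table


def group_frequency_change(
    trains: Sequence[EventTrain],
    labels: Sequence[ClassificationResult],
    pre: Interval,
    post: Interval,
) -> pd.DataFrame:
    """Mean +/- sem transient frequency per response group and window.

    Returns a table with one row per (group, window); groups with no
    members are omitted with a warning.
    """
    by_id = {r.neuron_id: r.label for r in labels}
    rows = []
    for group in (EXCITED, INHIBITED, NONRESPONSIVE):
        members = [t for t in trains if by_id.get(t.neuron_id) == group]
        if not members:
            logger.warning("group_frequency_change: no neurons labeled %r", group)
            continue
        for name, win in (("pre", pre), ("post", post)):
            freqs = np.array([transient_frequency(t, win) for t in members])
            sem = float(freqs.std(ddof=1) / np.sqrt(freqs.size)) if freqs.size > 1 else 0.0
            rows.append(
                {"group": group, "window": name, "n": freqs.size,
                 "mean_freq_per_min": float(freqs.mean()), "sem": sem}
            )
    return pd.DataFrame(rows, columns=["group", "window", "n", "mean_freq_per_min", "sem"])
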