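"""Place-preference (CPP) session analysis.

Occupancy tracks are segmented into chamber-staying episodes (stays longer
than 5 s by default); a neuron is a cocaine-associated context-encoding
(CACE) neuron when its per-episode transient frequency (or per-episode mean
trace value) differs between saline- and cocaine-chamber stays by a
two-sided Mann-Whitney U test.  Peri-entry alignment collects event rates
in 1-s bins around entries into a chamber (-5 to +5 s, entry at 0).  The
behavioral CPP score is the post-conditioning minus pre-conditioning time
in the cocaine-paired chamber, with the cocaine chamber assigned as the
less-preferred chamber at baseline and animals with a strong baseline bias
(< 25% preference for one chamber) flagged for exclusion.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .events import count_events
from .ranktests import mann_whitney_u
from .types import (
    CHAMBERS,
    COCAINE,
    EXCITED,
    INHIBITED,
    NONCLASSIFIABLE,
    NONRESPONSIVE,
    SALINE,
    BehaviorSummary,
    ClassificationResult,
    EpisodeConfig,
    EventTrain,
    FluorescenceTrace,
    OccupancyEpisode,
    OccupancyTrack,
    ParameterError,
)

__all__ = [
    "extract_episodes",
    "episode_frequencies",
    "classify_cace",
    "chamber_entries",
    "peri_entry_matrix",
    "peri_entry_summary",
    "cpp_score",
]

logger = logging.getLogger(__name__)


def _runs(track: OccupancyTrack) -> List[Tuple[str, float, float]]:
    """Maximal constant-chamber runs as (chamber, start, end), half-open."""
    ch = track.chambers
    change = np.flatnonzero(ch[1:] != ch[:-1]) + 1
    starts = np.concatenate([[0], change])
    bounds = np.append(track.times[starts], track.session_end)
    return [
        (str(ch[i]), float(bounds[k]), float(bounds[k + 1]))
        for k, i in enumerate(starts)
    ]


def extract_episodes(track: OccupancyTrack, cfg: Optional[EpisodeConfig] = None) -> List[OccupancyEpisode]:
    """Chamber-staying episodes: constant-chamber runs longer than min_dwell.

    Runs of duration <= ``min_dwell`` (default 5 s) are excluded from the
    episode list; they still count as visits for entry detection, which
    works on the raw track.
    """
    cfg = cfg or EpisodeConfig()
    return [
        OccupancyEpisode(chamber=c, start_s=a, end_s=b)
        for c, a, b in _runs(track)
        if (b - a) > cfg.min_dwell
    ]


def episode_frequencies(
    train: EventTrain, episodes: Sequence[OccupancyEpisode]
) -> Dict[str, np.ndarray]:
    """Per-episode transient frequency (events/min) grouped by chamber."""
    out: Dict[str, List[float]] = {c: [] for c in CHAMBERS}
    for ep in episodes:
        n = count_events(train, (ep.start_s, ep.end_s))
        out[ep.chamber].append(n / ep.duration_s * 60.0)
    return {c: np.asarray(v) for c, v in out.items()}


def _episode_trace_means(
    trace: FluorescenceTrace, episodes: Sequence[OccupancyEpisode]
) -> Dict[str, np.ndarray]:
    out: Dict[str, List[float]] = {c: [] for c in CHAMBERS}
    for ep in episodes:
        out[ep.chamber].append(float(trace.segment(ep.start_s, ep.end_s).mean()))
    return {c: np.asarray(v) for c, v in out.items()}


def classify_cace(
    signal,
    episodes: Sequence[OccupancyEpisode],
    cfg: Optional[EpisodeConfig] = None,
    method: str = "transients",
) -> ClassificationResult:
    """Label a neuron as cocaine-chamber excited / inhibited / nonresponsive.

    ``signal`` is an :class:`EventTrain` for ``method='transients'``
    (per-episode transient frequencies are compared) or a
    :class:`FluorescenceTrace` for ``method='traces'`` (per-episode mean
    trace values).  Neurons with fewer than ``min_episodes_per_chamber``
    episodes in either chamber are labelled ``nonclassifiable``.
    """
    cfg = cfg or EpisodeConfig()
    if method == "transients":
        if not isinstance(signal, EventTrain):
            raise ParameterError("method 'transients' needs an EventTrain")
        groups = episode_frequencies(signal, episodes)
    elif method == "traces":
        if not isinstance(signal, FluorescenceTrace):
            raise ParameterError("method 'traces' needs a FluorescenceTrace")
        groups = _episode_trace_means(signal, episodes)
    else:
        raise ParameterError(f"unknown method {method!r}")

    nid = signal.neuron_id
    sal, coc = groups[SALINE], groups[COCAINE]
    if min(sal.size, coc.size) < cfg.min_episodes_per_chamber:
        return ClassificationResult(neuron_id=nid, label=NONCLASSIFIABLE,
                                    method=method, phase=None)
    res = mann_whitney_u(coc, sal, max_exact_total=cfg.exact_max_n)
    if res.p_value < cfg.alpha:
        # U above its null mean means the cocaine-chamber values rank higher
        label = EXCITED if res.statistic > coc.size * sal.size / 2.0 else INHIBITED
    else:
        label = NONRESPONSIVE
    return ClassificationResult(
        neuron_id=nid, label=label, method=method,
        statistic=float(res.statistic), p_value=float(res.p_value),
    )


def chamber_entries(
    track: OccupancyTrack,
    target_chamber: str,
    cfg: Optional[EpisodeConfig] = None,
    min_flanking_dwell: float = 0.0,
) -> np.ndarray:
    """Entry times into ``target_chamber``.

    Every transition into the target chamber counts, regardless of how long
    the preceding or following stay lasted (set ``min_flanking_dwell`` > 0
    to require a minimum dwell on both sides).  Entries whose +/- peri
    window does not fit inside the session are dropped.
    """
    cfg = cfg or EpisodeConfig()
    if target_chamber not in CHAMBERS:
        raise ParameterError(f"unknown chamber {target_chamber!r}")
    runs = _runs(track)
    entries = []
    for k in range(1, len(runs)):
        ch, a, b = runs[k]
        if ch != target_chamber:
            continue
        prev_dur = runs[k - 1][2] - runs[k - 1][1]
        if min_flanking_dwell > 0 and (prev_dur < min_flanking_dwell or (b - a) < min_flanking_dwell):
            continue
        entries.append(a)
    entries = np.asarray(entries)
    lo = track.session_start + cfg.peri_window
    hi = track.session_end - cfg.peri_window
    return entries[(entries >= lo) & (entries <= hi)]


def peri_entry_matrix(
    train: EventTrain,
    track: OccupancyTrack,
    target_chamber: str = COCAINE,
    cfg: Optional[EpisodeConfig] = None,
    min_flanking_dwell: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Event rates around chamber entries.

    Returns ``(matrix, bin_edges, pre_post)`` where ``matrix`` is
    entries x bins of event rates (events/min) in ``peri_bin``-s bins over
    ``[-peri_window, +peri_window)`` relative to each entry, and
    ``pre_post`` holds this neuron's mean rate over the pre-entry
    ``[-peri_window, 0)`` and post-entry ``[0, +peri_window)`` windows.
    """
    cfg = cfg or EpisodeConfig()
    entries = chamber_entries(track, target_chamber, cfg, min_flanking_dwell)
    edges = np.arange(-cfg.peri_window, cfg.peri_window + cfg.peri_bin / 2, cfg.peri_bin)
    n_bins = edges.size - 1
    if entries.size == 0:
        logger.warning("peri_entry_matrix: no valid entries into %s", target_chamber)
        return np.empty((0, n_bins)), edges, {"pre": np.nan, "post": np.nan}
    mat = np.empty((entries.size, n_bins))
    for i, e in enumerate(entries):
        rel = train.event_times - e
        counts, _ = np.histogram(rel, bins=edges)
        mat[i] = counts / cfg.peri_bin * 60.0
    pre_rate = float(np.mean(
        [count_events(train, (e - cfg.peri_window, e)) for e in entries]
    )) / cfg.peri_window * 60.0
    post_rate = float(np.mean(
        [count_events(train, (e, e + cfg.peri_window)) for e in entries]
    )) / cfg.peri_window * 60.0
    return mat, edges, {"pre": pre_rate, "post": post_rate}


def peri_entry_summary(
    trains: Sequence[EventTrain],
    track: OccupancyTrack,
    target_chamber: str = COCAINE,
    cfg: Optional[EpisodeConfig] = None,
) -> Dict[str, np.ndarray]:
    """Group-level peri-entry curve: mean over entries, then over neurons."""
    cfg = cfg or EpisodeConfig()
    curves, pres, posts = [], [], []
    edges = None
    for train in trains:
        mat, edges, pp = peri_entry_matrix(train, track, target_chamber, cfg)
        if mat.shape[0] == 0:
            continue
        curves.append(mat.mean(axis=0))
        pres.append(pp["pre"])
        posts.append(pp["post"])
    if not curves:
        return {"bin_edges": edges if edges is not None else np.empty(0),
                "mean_curve": np.empty(0), "pre": np.empty(0), "post": np.empty(0)}
    return {
        "bin_edges": edges,
        "mean_curve": np.mean(curves, axis=0),
        "pre": np.asarray(pres),
        "post": np.asarray(posts),
    }


def cpp_score(
    pre_track: OccupancyTrack,
    post_track: OccupancyTrack,
    assign_by_preference: bool = True,
    exclusion_threshold: float = 0.25,
) -> BehaviorSummary:
    """Behavioral place-preference score for one animal.

    The cocaine-paired chamber is the *less preferred* chamber of the
    pre-conditioning session (unless ``assign_by_preference`` is False, in
    which case the track's own cocaine label is taken as given); the score
    is post-conditioning minus pre-conditioning time in that chamber, in
    seconds.  Animals whose baseline preference for either chamber falls
    below ``exclusion_threshold`` are flagged as excluded.
    """
    pre_times = pre_track.time_per_chamber()
    total_pre = sum(pre_times.values())
    if assign_by_preference:
        cocaine_chamber = min(CHAMBERS, key=lambda c: pre_times[c])
    else:
        cocaine_chamber = COCAINE
    minority_fraction = min(pre_times.values()) / total_pre
    pre_c = pre_times[cocaine_chamber]
    post_c = post_track.time_per_chamber()[cocaine_chamber]
    return BehaviorSummary(
        pre_time_cocaine_s=pre_c,
        post_time_cocaine_s=post_c,
        cpp_score_s=post_c - pre_c,
        baseline_preference_fraction=minority_fraction,
        excluded=bool(minority_fraction < exclusion_threshold),
        cocaine_chamber=cocaine_chamber,
    )
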