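"""Core containers and configuration objects.

Time conventions used throughout the package:

* all times are seconds; event *rates* are events per minute (the unit in
  which transient frequencies are conventionally plotted);
* every window / episode is half-open ``[t0, t1)`` so an event sitting on a
  shared boundary is counted exactly once;
* traces are uniformly sampled; frame ``i`` of a trace covers
  ``start_time + i / sampling_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CatransError",
    "FormatError",
    "ParameterError",
    "DegenerateInputError",
    "NotClassifiableError",
    "EXCITED",
    "INHIBITED",
    "NONRESPONSIVE",
    "NONCLASSIFIABLE",
    "SALINE",
    "COCAINE",
    "CHAMBERS",
    "FluorescenceTrace",
    "EventTrain",
    "OccupancyTrack",
    "OccupancyEpisode",
    "PhaseWindows",
    "DeconvParams",
    "PermutationConfig",
    "TraceTestConfig",
    "EpisodeConfig",
    "ClassificationResult",
    "BehaviorSummary",
]


class CatransError(Exception):
    """Base class for package errors."""


class FormatError(CatransError):
    """Malformed input file or table (CLI exit code 2)."""


class ParameterError(CatransError):
    """Invalid parameter or window definition (CLI exit code 3)."""


class DegenerateInputError(ParameterError):
    """Input that makes the requested statistic undefined (e.g. zero variance)."""


class NotClassifiableError(CatransError):
    """Neuron has too little signal for the requested test.

    Distinct from a parameter error: the inputs are valid, the neuron simply
    cannot be assessed (too few transients to permute, too few chamber
    episodes to rank).  Callers typically catch this and record a
    ``nonclassifiable`` label.
    """


# classification labels
EXCITED = "excited"
INHIBITED = "inhibited"
NONRESPONSIVE = "nonresponsive"
NONCLASSIFIABLE = "nonclassifiable"

# chamber labels for place-preference sessions
SALINE = "saline"
COCAINE = "cocaine"
CHAMBERS = (SALINE, COCAINE)


def _as_interval(iv: Sequence[float], name: str = "interval") -> Tuple[float, float]:
    a, b = float(iv[0]), float(iv[1])
    if not (np.isfinite(a) and np.isfinite(b)) or b <= a:
        raise ParameterError(f"{name} must be a finite interval with t1 > t0, got ({a}, {b})")
    return a, b


@dataclass
class FluorescenceTrace:
    """One neuron's dF/noise values on a uniform time grid."""

    neuron_id: str
    start_time: float
    sampling_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"trace {self.neuron_id}: non-finite values")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.sampling_rate

    def frame_slice(self, t0: float, t1: float) -> slice:
        """Frame indices whose sample times fall in ``[t0, t1)``."""
        a, b = _as_interval((t0, t1), "window")
        # first frame with time >= a, first frame with time >= b
        i0 = int(np.ceil((a - self.start_time) * self.sampling_rate - 1e-9))
        i1 = int(np.ceil((b - self.start_time) * self.sampling_rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.n_frames)
        return slice(i0, i1)

    def segment(self, t0: float, t1: float) -> np.ndarray:
        sl = self.frame_slice(t0, t1)
        if sl.start >= sl.stop:
            raise ParameterError(
                f"window [{t0}, {t1}) does not overlap trace "
                f"[{self.start_time}, {self.end_time})"
            )
        return self.values[sl]


@dataclass
class EventTrain:
    """Transient (event) timestamps of one neuron within a session."""

    neuron_id: str
    event_times: np.ndarray
    span: Tuple[float, float]

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.span = (float(self.span[0]), float(self.span[1]))
        if self.event_times.ndim != 1:
            raise ParameterError("event_times must be one-dimensional")
        if self.event_times.size and np.any(np.diff(self.event_times) <= 0):
            raise FormatError(f"train {self.neuron_id}: event times not strictly increasing")
        t0, t1 = self.span
        if t1 <= t0:
            raise ParameterError("span must satisfy t1 > t0")
        if self.event_times.size and (
            self.event_times[0] < t0 - 1e-9 or self.event_times[-1] >= t1 + 1e-9
        ):
            raise FormatError(f"train {self.neuron_id}: events outside span {self.span}")

    @property
    def n_events(self) -> int:
        return self.event_times.size


@dataclass
class OccupancyTrack:
    """Time-stamped chamber labels for a two-chamber place-preference session."""

    times: np.ndarray
    chambers: np.ndarray
    session_end: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.chambers = np.asarray(self.chambers, dtype=object)
        if self.times.size == 0:
            raise FormatError("occupancy track is empty")
        if self.times.size != self.chambers.size:
            raise FormatError("occupancy track: times and chambers differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("occupancy track: times not strictly increasing")
        bad = set(self.chambers.tolist()) - set(CHAMBERS)
        if bad:
            raise FormatError(f"occupancy track: unknown chamber labels {sorted(bad)}")
        if self.session_end is None:
            # extrapolate one sampling interval past the last sample
            dt = float(np.median(np.diff(self.times))) if self.times.size > 1 else 0.1
            self.session_end = float(self.times[-1]) + dt
        self.session_end = float(self.session_end)
        if self.session_end <= self.times[-1]:
            raise ParameterError("session_end must lie past the last sample")

    @property
    def session_start(self) -> float:
        return float(self.times[0])

    def time_per_chamber(self) -> dict:
        """Total occupancy time (s) per chamber over the whole session."""
        bounds = np.append(self.times, self.session_end)
        dur = np.diff(bounds)
        return {c: float(dur[self.chambers == c].sum()) for c in CHAMBERS}

    def swapped(self) -> "OccupancyTrack":
        """Track with saline and cocaine labels exchanged."""
        mapping = {SALINE: COCAINE, COCAINE: SALINE}
        return OccupancyTrack(
            times=self.times.copy(),
            chambers=np.array([mapping[c] for c in self.chambers], dtype=object),
            session_end=self.session_end,
        )


@dataclass(frozen=True)
class OccupancyEpisode:
    """One maximal constant-chamber stay, half-open ``[start_s, end_s)``."""

    chamber: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseWindows:
    """Recording windows relative to the injection at t = 0 s.

    Defaults follow the standard acute-administration layout: a 10-min
    pre-injection baseline, the 0-10 min post-injection initial phase and
    the 50-60 min decay phase.
    """

    pre: Tuple[float, float] = (-600.0, 0.0)
    initial: Tuple[float, float] = (0.0, 600.0)
    decay: Tuple[float, float] = (3000.0, 3600.0)

    def __post_init__(self) -> None:
        ivs = [
            _as_interval(self.pre, "pre"),
            _as_interval(self.initial, "initial"),
            _as_interval(self.decay, "decay"),
        ]
        object.__setattr__(self, "pre", ivs[0])
        object.__setattr__(self, "initial", ivs[1])
        object.__setattr__(self, "decay", ivs[2])
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ParameterError("phase windows must be ordered and non-overlapping")

    @property
    def session_span(self) -> Tuple[float, float]:
        return (self.pre[0], self.decay[1])


def _duration(iv: Tuple[float, float]) -> float:
    return iv[1] - iv[0]


@dataclass(frozen=True)
class DeconvParams:
    """Sparse non-negative AR(1) deconvolution and event-calling settings.

    ``ar_coefficient`` is the per-frame calcium decay gamma; the default
    corresponds to a 1-s indicator decay constant at 10 Hz
    (gamma = exp(-1 / (tau * rate))), a GCaMP6m-scale value.
    """

    ar_coefficient: float = float(np.exp(-0.1))
    sparsity_penalty: float = 0.0
    event_threshold_k: float = 2.0
    min_separation: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.ar_coefficient < 1.0:
            raise ParameterError("ar_coefficient must lie in (0, 1)")
        if self.sparsity_penalty < 0:
            raise ParameterError("sparsity_penalty must be nonnegative")
        if self.event_threshold_k <= 0:
            raise ParameterError("event_threshold_k must be positive")
        if self.min_separation < 1:
            raise ParameterError("min_separation must be >= 1 frame")

    @staticmethod
    def from_tau(tau: float, sampling_rate: float = 10.0, **kw) -> "DeconvParams":
        if tau <= 0 or sampling_rate <= 0:
            raise ParameterError("tau and sampling_rate must be positive")
        return DeconvParams(ar_coefficient=float(np.exp(-1.0 / (tau * sampling_rate))), **kw)


@dataclass(frozen=True)
class PermutationConfig:
    """Intertransient-interval shuffling null for injection responses."""

    n_permutations: int = 10_000
    lower_percentile: float = 1.0
    upper_percentile: float = 99.0
    seed: int = 0
    min_events: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_percentile < self.upper_percentile < 100.0:
            raise ParameterError("percentiles must satisfy 0 < lower < upper < 100")
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be positive")
        if self.min_events < 3:
            raise ParameterError("min_events must be >= 3 (need at least two intervals)")


@dataclass(frozen=True)
class TraceTestConfig:
    """Binned z-scored trace comparison (paired signed-rank) settings."""

    n_bins: int = 10
    bin_length: float = 60.0
    alpha: float = 0.05
    zscore_mode: str = "joint"  # "joint" (default) or "per_window"

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.bin_length <= 0:
            raise ParameterError("need n_bins >= 2 and positive bin_length")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.zscore_mode not in ("joint", "per_window"):
            raise ParameterError("zscore_mode must be 'joint' or 'per_window'")

    @property
    def window_duration(self) -> float:
        return self.n_bins * self.bin_length


@dataclass(frozen=True)
class EpisodeConfig:
    """Chamber-episode extraction and context-encoding test settings."""

    min_dwell: float = 5.0
    min_episodes_per_chamber: int = 3
    alpha: float = 0.05
    peri_window: float = 5.0
    peri_bin: float = 1.0
    exact_max_n: int = 20

    def __post_init__(self) -> None:
        if self.min_dwell <= 0:
            raise ParameterError("min_dwell must be positive")
        if self.min_episodes_per_chamber < 1:
            raise ParameterError("min_episodes_per_chamber must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.peri_window <= 0 or self.peri_bin <= 0:
            raise ParameterError("peri_window and peri_bin must be positive")


@dataclass
class ClassificationResult:
    """Per-neuron response label with the statistic that produced it.

    ``statistic`` is the actual transient change (count difference) for the
    permutation method, the signed-rank statistic for the trace method and
    the Mann-Whitney U for chamber comparisons.  ``null_low``/``null_high``
    hold the 1st/99th-percentile thresholds of the shuffled-change
    distribution (permutation method only).
    """

    neuron_id: str
    label: str
    method: str
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    null_low: Optional[float] = None
    null_high: Optional[float] = None
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (EXCITED, INHIBITED, NONRESPONSIVE, NONCLASSIFIABLE):
            raise ParameterError(f"unknown label {self.label!r}")


@dataclass
class BehaviorSummary:
    """Place-preference behavior for one animal."""

    pre_time_cocaine_s: float
    post_time_cocaine_s: float
    cpp_score_s: float
    baseline_preference_fraction: float
    excluded: bool
    cocaine_chamber: str = COCAINE
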