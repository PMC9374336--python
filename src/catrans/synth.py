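"""Synthetic calcium-imaging sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-neuron transients are inhomogeneous-Poisson event trains whose
rate is multiplied up or down after an injection (or inside the
cocaine-paired chamber), fluorescence is the event train convolved with an
exponential-decay calcium impulse response plus white Gaussian noise, and
place-preference behavior is an alternating two-chamber occupancy sequence
with shifted-exponential dwell times straddling the 5-s episode threshold.

Baseline rates are heterogeneous across neurons (log-normal, median 4
events/min, sigma_log 0.5 by default): a fixed population rate would make
the permutation nulls unrealistically uniform.

Randomness is split into independent substreams (one behavior stream plus
one stream per neuron) spawned from the single session seed, so changing
``n_neurons`` does not perturb the behavior trajectory or earlier neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import (
    COCAINE,
    EXCITED,
    INHIBITED,
    SALINE,
    EventTrain,
    FluorescenceTrace,
    OccupancyTrack,
    ParameterError,
    PhaseWindows,
)

__all__ = [
    "SynthSessionParams",
    "SynthCPPParams",
    "simulate_injection_session",
    "simulate_cpp_session",
    "events_to_trace",
    "poisson_train",
]

NONE_CLASS = "none"


def _check_rate(x: float, name: str) -> None:
    if not np.isfinite(x) or x < 0:
        raise ParameterError(f"{name} must be finite and nonnegative, got {x}")


@dataclass(frozen=True)
class SynthSessionParams:
    """Injection-session generator settings.

    ``baseline_rate`` is the population *median* rate (events/min); each
    neuron's own baseline is drawn log-normal around it with log-sd
    ``baseline_sigma_log`` (set to 0 for identical rates).  Default response
    structure mirrors the asymmetry seen after acute cocaine: more neurons
    inhibited than excited.
    """

    n_neurons: int = 100
    baseline_rate: float = 4.0
    baseline_sigma_log: float = 0.5
    frac_excited: float = 0.15
    frac_inhibited: float = 0.30
    multiplier_excited: float = 2.5
    multiplier_inhibited: float = 0.4
    kernel_decay_tau: float = 1.0
    noise_sd: float = 0.3
    sampling_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ParameterError("n_neurons must be >= 1")
        _check_rate(self.baseline_rate, "baseline_rate")
        _check_rate(self.noise_sd, "noise_sd")
        if self.baseline_sigma_log < 0:
            raise ParameterError("baseline_sigma_log must be >= 0")
        if not 0 <= self.frac_excited <= 1 or not 0 <= self.frac_inhibited <= 1:
            raise ParameterError("class fractions must lie in [0, 1]")
        if self.frac_excited + self.frac_inhibited > 1 + 1e-12:
            raise ParameterError("frac_excited + frac_inhibited must be <= 1")
        if not self.multiplier_excited >= 1:
            raise ParameterError("multiplier_excited must be >= 1")
        if not 0 < self.multiplier_inhibited <= 1:
            raise ParameterError("multiplier_inhibited must lie in (0, 1]")
        if self.kernel_decay_tau <= 0 or self.sampling_rate <= 0:
            raise ParameterError("kernel_decay_tau and sampling_rate must be positive")


@dataclass(frozen=True)
class SynthCPPParams:
    """Place-preference session generator settings.

    Occupancy alternates between the two chambers with dwell times
    ``min_dwell_floor + Exp(mean_dwell - min_dwell_floor)`` so that stays
    both below and above the 5-s episode threshold occur.  Chamber-modulated
    neurons change rate by ``multiplier_excited`` / ``multiplier_inhibited``
    while the animal is in the cocaine chamber.
    """

    n_neurons: int = 100
    baseline_rate: float = 4.0
    baseline_sigma_log: float = 0.5
    frac_chamber_excited: float = 0.05
    frac_chamber_inhibited: float = 0.17
    multiplier_excited: float = 2.5
    multiplier_inhibited: float = 0.3
    session_length: float = 900.0
    mean_dwell: float = 20.0
    min_dwell_floor: float = 2.0
    kernel_decay_tau: float = 1.0
    noise_sd: float = 0.3
    sampling_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ParameterError("n_neurons must be >= 1")
        _check_rate(self.baseline_rate, "baseline_rate")
        if not 0 <= self.frac_chamber_excited <= 1 or not 0 <= self.frac_chamber_inhibited <= 1:
            raise ParameterError("class fractions must lie in [0, 1]")
        if self.frac_chamber_excited + self.frac_chamber_inhibited > 1 + 1e-12:
            raise ParameterError("class fractions must sum to <= 1")
        if not self.multiplier_excited >= 1:
            raise ParameterError("multiplier_excited must be >= 1")
        if not 0 < self.multiplier_inhibited <= 1:
            raise ParameterError("multiplier_inhibited must lie in (0, 1]")
        if self.min_dwell_floor <= 0 or self.mean_dwell <= self.min_dwell_floor:
            raise ParameterError("need 0 < min_dwell_floor < mean_dwell")
        if self.session_length < 2 * self.min_dwell_floor:
            raise ParameterError("session_length shorter than two minimal dwells")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")


def poisson_train(
    rate_per_min: float,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    min_gap: Optional[float] = None,
) -> np.ndarray:
    """Homogeneous Poisson event times in [t0, t1), optionally thinned so
    consecutive events are at least ``min_gap`` seconds apart."""
    _check_rate(rate_per_min, "rate")
    lam = rate_per_min / 60.0 * (t1 - t0)
    n = rng.poisson(lam)
    times = np.sort(t0 + rng.random(n) * (t1 - t0))
    if min_gap is not None and times.size > 1:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= min_gap:
                keep.append(i)
        times = times[keep]
    return times


def _piecewise_poisson(
    segments: List[Tuple[float, float, float]], rng: np.random.Generator
) -> np.ndarray:
    """Events from a piecewise-constant-rate process; segments are
    (t0, t1, rate_per_min)."""
    parts = [poisson_train(r, a, b, rng) for a, b, r in segments if b > a]
    times = np.concatenate(parts) if parts else np.empty(0)
    times = np.unique(times)  # exact ties have probability zero; guard anyway
    return times


def events_to_trace(
    event_times: np.ndarray,
    span: Tuple[float, float],
    sampling_rate: float,
    tau: float,
    noise_sd: float,
    rng: Optional[np.random.Generator] = None,
    neuron_id: str = "n0",
) -> FluorescenceTrace:
    """Render an event train as a dF/noise trace.

    Each event contributes a unit-amplitude exponential kernel
    ``exp(-t / tau)`` placed at its nearest frame; independent Gaussian
    noise of sd ``noise_sd`` is added per frame.
    """
    t0, t1 = span
    n_frames = int(round((t1 - t0) * sampling_rate))
    impulses = np.zeros(n_frames)
    if len(event_times):
        idx = np.round((np.asarray(event_times) - t0) * sampling_rate).astype(int)
        idx = idx[(idx >= 0) & (idx < n_frames)]
        np.add.at(impulses, idx, 1.0)
    gamma = np.exp(-1.0 / (tau * sampling_rate))
    values = lfilter([1.0], [1.0, -gamma], impulses)
    if noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when noise_sd > 0")
        values = values + rng.normal(0.0, noise_sd, size=n_frames)
    return FluorescenceTrace(
        neuron_id=neuron_id, start_time=t0, sampling_rate=sampling_rate, values=values
    )


def _assign_classes(n: int, frac_exc: float, frac_inh: float) -> List[str]:
    n_exc = int(round(frac_exc * n))
    n_inh = int(round(frac_inh * n))
    return [EXCITED] * n_exc + [INHIBITED] * n_inh + [NONE_CLASS] * (n - n_exc - n_inh)


def _neuron_rngs(seed: int, n_neurons: int):
    """One behavior stream plus one independent stream per neuron."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_neurons + 1)
    return np.random.default_rng(children[0]), [np.random.default_rng(c) for c in children[1:]]


def simulate_injection_session(
    params: SynthSessionParams,
    windows: Optional[PhaseWindows] = None,
    include_traces: bool = True,
) -> Tuple[List[FluorescenceTrace], List[EventTrain], pd.DataFrame]:
    """Simulate one injection session.

    Every neuron fires as a homogeneous Poisson process at its baseline rate
    before the injection (t < 0) and at baseline x multiplier afterwards
    (multiplier 1 for unmodulated neurons).  Returns traces, event trains
    and the ground-truth table (neuron_id, true_class, baseline_rate,
    multiplier).  ``include_traces=False`` skips trace rendering (event-only
    studies at large n); the trains are unchanged either way.
    """
    windows = windows or PhaseWindows()
    span = windows.session_span
    _, rngs = _neuron_rngs(params.seed, params.n_neurons)
    classes = _assign_classes(params.n_neurons, params.frac_excited, params.frac_inhibited)

    traces, trains, rows = [], [], []
    for i, (cls, rng) in enumerate(zip(classes, rngs)):
        nid = f"n{i:04d}"
        base = params.baseline_rate
        if params.baseline_sigma_log > 0:
            base = float(base * np.exp(rng.normal(0.0, params.baseline_sigma_log)))
        mult = {EXCITED: params.multiplier_excited,
                INHIBITED: params.multiplier_inhibited,
                NONE_CLASS: 1.0}[cls]
        segments = [(span[0], 0.0, base), (0.0, span[1], base * mult)]
        ev = _piecewise_poisson(segments, rng)
        trains.append(EventTrain(neuron_id=nid, event_times=ev, span=span))
        if include_traces:
            traces.append(
                events_to_trace(ev, span, params.sampling_rate, params.kernel_decay_tau,
                                params.noise_sd, rng, neuron_id=nid)
            )
        rows.append({"neuron_id": nid, "true_class": cls,
                     "baseline_rate": base, "multiplier": mult})
    return traces, trains, pd.DataFrame(rows)


def _dwell_sequence(params: SynthCPPParams, rng: np.random.Generator):
    """Alternating chamber episodes covering [0, session_length)."""
    episodes = []
    t = 0.0
    chamber = SALINE
    while t < params.session_length:
        dwell = params.min_dwell_floor + rng.exponential(
            params.mean_dwell - params.min_dwell_floor
        )
        end = min(t + dwell, params.session_length)
        episodes.append((chamber, t, end))
        t = end
        chamber = COCAINE if chamber == SALINE else SALINE
    return episodes


def simulate_cpp_session(
    params: SynthCPPParams,
) -> Tuple[OccupancyTrack, List[EventTrain], pd.DataFrame]:
    """Simulate one free-exploration place-preference session.

    Returns the occupancy track (sampled at ``sampling_rate``), the event
    trains and the ground-truth table.  Chamber-excited / -inhibited neurons
    multiply their rate while the animal occupies the cocaine chamber.
    """
    behavior_rng, rngs = _neuron_rngs(params.seed, params.n_neurons)
    episodes = _dwell_sequence(params, behavior_rng)

    times = np.arange(0.0, params.session_length, 1.0 / params.sampling_rate)
    starts = np.array([e[1] for e in episodes])
    labels = np.array([e[0] for e in episodes], dtype=object)
    track = OccupancyTrack(
        times=times,
        chambers=labels[np.searchsorted(starts, times, side="right") - 1],
        session_end=params.session_length,
    )

    classes = _assign_classes(
        params.n_neurons, params.frac_chamber_excited, params.frac_chamber_inhibited
    )
    span = (0.0, params.session_length)
    trains, rows = [], []
    for i, (cls, rng) in enumerate(zip(classes, rngs)):
        nid = f"n{i:04d}"
        base = params.baseline_rate
        if params.baseline_sigma_log > 0:
            base = float(base * np.exp(rng.normal(0.0, params.baseline_sigma_log)))
        mult = {EXCITED: params.multiplier_excited,
                INHIBITED: params.multiplier_inhibited,
                NONE_CLASS: 1.0}[cls]
        segments = [
            (a, b, base * mult if ch == COCAINE else base) for ch, a, b in episodes
        ]
        ev = _piecewise_poisson(segments, rng)
        trains.append(EventTrain(neuron_id=nid, event_times=ev, span=span))
        rows.append({"neuron_id": nid, "true_class": cls,
                     "baseline_rate": base, "multiplier": mult})
    return track, trains, pd.DataFrame(rows)
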