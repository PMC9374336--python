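"""Transient detection: z-scoring, sparse non-negative deconvolution and
thresholded event calling.

The deconvolution step inverts the AR(1) calcium dynamics
``c_t = gamma * c_{t-1} + s_t`` by solving

    minimize  1/2 ||y - c||^2 + lam * sum(s)   s.t.  s >= 0

with the online active-set (pool adjacent violators) scheme: frames are
processed left to right, each starting its own pool with the within-pool
solution ``c_t = v_i * gamma^(t - t_i)``, and adjacent pools are merged
whenever the preceding pool's extrapolated value exceeds the next pool's
start (the constraint ``s >= 0`` would be violated).  Because the AR(1)
impulse response is nonnegative, ``s >= 0`` implies ``c >= 0``; only a
leading run of pools can come out negative and is clamped to zero.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .types import (
    DeconvParams,
    DegenerateInputError,
    EventTrain,
    FluorescenceTrace,
    ParameterError,
)

__all__ = [
    "zscore_trace",
    "estimate_noise_sd",
    "deconvolve_trace",
    "detect_transients",
    "extract_events",
    "count_events",
    "transient_frequency",
]


def zscore_trace(
    trace: FluorescenceTrace, reference_window: Optional[Tuple[float, float]] = None
) -> FluorescenceTrace:
    """Standardize a trace to zero mean and unit (population) sd.

    If ``reference_window`` is given, the mean and sd are computed on that
    half-open interval only but applied to the whole trace.
    """
    if reference_window is not None:
        ref = trace.segment(*reference_window)
    else:
        ref = trace.values
    mu = float(ref.mean())
    sd = float(ref.std(ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError(
            f"trace {trace.neuron_id}: zero variance in the z-scoring reference"
        )
    return FluorescenceTrace(
        neuron_id=trace.neuron_id,
        start_time=trace.start_time,
        sampling_rate=trace.sampling_rate,
        values=(trace.values - mu) / sd,
    )


def estimate_noise_sd(trace: FluorescenceTrace) -> float:
    """Noise sd from the median absolute deviation of the first difference.

    The first difference of an AR(1) calcium trace is dominated by the white
    noise (variance ``2 * sd^2``) except at sparse transient onsets, which
    the median ignores; dividing MAD by ``sqrt(2) * 0.6745`` recovers the
    per-frame noise sd under Gaussian noise.
    """
    if trace.n_frames < 2:
        raise ParameterError("need at least two frames to estimate noise")
    d = np.diff(trace.values)
    mad = float(np.median(np.abs(d - np.median(d))))
    return mad / (np.sqrt(2.0) * 0.6745)


def deconvolve_trace(trace: FluorescenceTrace, params: DeconvParams) -> np.ndarray:
    """Infer the nonnegative activity sequence ``s`` underlying a trace.

    Returns an array aligned to the trace frames; ``s[t]`` is the inferred
    transient amplitude added at frame ``t``.
    """
    y = np.asarray(trace.values, dtype=float)
    if y.size < 10:
        raise ParameterError("trace too short to deconvolve (< 10 frames)")
    return _oasis_ar1(y, params.ar_coefficient, params.sparsity_penalty)


def _oasis_ar1(y: np.ndarray, gamma: float, lam: float) -> np.ndarray:
    if not 0.0 < gamma < 1.0:
        raise ParameterError("ar_coefficient must lie in (0, 1)")
    T = y.size
    # the l1 penalty on s is linear in c: lam * sum(s) =
    # lam * ((1 - gamma) * sum(c[:-1]) + c[-1]); fold it into the target
    yt = y.astype(float).copy()
    if lam > 0:
        yt[:-1] -= lam * (1.0 - gamma)
        yt[-1] -= lam

    # pools: value v (fitted start amplitude), weight w, start t, length l
    v = np.empty(T)
    w = np.empty(T)
    t = np.empty(T, dtype=np.intp)
    l = np.empty(T, dtype=np.intp)
    n = 0  # number of pools
    for i in range(T):
        v[n], w[n], t[n], l[n] = yt[i], 1.0, i, 1
        n += 1
        # merge while the previous pool extrapolates above the new pool start
        while n > 1 and v[n - 1] < gamma ** l[n - 2] * v[n - 2]:
            g = gamma ** l[n - 2]
            vn = (w[n - 2] * v[n - 2] + g * w[n - 1] * v[n - 1]) / (w[n - 2] + g * g * w[n - 1])
            w[n - 2] += g * g * w[n - 1]
            v[n - 2] = vn
            l[n - 2] += l[n - 1]
            n -= 1

    # s >= 0 implies every pool start is >= gamma^l * (previous), hence only
    # a leading run of pools can be negative; its constrained optimum is 0
    v[:n] = np.maximum(v[:n], 0.0)

    c = np.empty(T)
    for k in range(n):
        c[t[k]: t[k] + l[k]] = v[k] * gamma ** np.arange(l[k])
    s = np.empty(T)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    # within-pool entries are zero by construction; clip rounding dust
    s[s < 1e-12] = 0.0
    return s


def deconvolution_objective(y: np.ndarray, s: np.ndarray, gamma: float, lam: float) -> float:
    """Objective value 1/2 ||y - c||^2 + lam * sum(s) for activity ``s``."""
    from scipy.signal import lfilter

    c = lfilter([1.0], [1.0, -gamma], s)
    return 0.5 * float(np.sum((np.asarray(y) - c) ** 2)) + lam * float(np.sum(s))


def detect_transients(
    activity: np.ndarray,
    noise_sd: float,
    params: DeconvParams,
    *,
    start_time: float = 0.0,
    sampling_rate: float = 10.0,
    neuron_id: str = "n0",
) -> EventTrain:
    """Call transients at local maxima of the activity above threshold.

    A frame is an event candidate when it is a local maximum of ``s`` and
    exceeds ``event_threshold_k * noise_sd``.  Candidates closer than
    ``min_separation`` frames are merged keeping the larger amplitude.
    """
    s = np.asarray(activity, dtype=float)
    T = s.size
    span = (start_time, start_time + max(T, 1) / sampling_rate)
    if T == 0:
        return EventTrain(neuron_id=neuron_id, event_times=np.empty(0), span=span)
    thr = params.event_threshold_k * max(noise_sd, 0.0)

    left = np.empty(T)
    right = np.empty(T)
    left[0], left[1:] = -np.inf, s[:-1]
    right[-1], right[:-1] = -np.inf, s[1:]
    cand = np.flatnonzero((s > thr) & (s > left) & (s >= right))

    # non-maximum suppression: keep larger peaks, drop neighbours closer
    # than min_separation frames
    order = cand[np.argsort(s[cand])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= params.min_separation for k in kept):
            kept.append(int(idx))
    kept.sort()
    times = start_time + np.asarray(kept, dtype=float) / sampling_rate
    return EventTrain(neuron_id=neuron_id, event_times=times, span=span)


def extract_events(trace: FluorescenceTrace, params: Optional[DeconvParams] = None) -> EventTrain:
    """Full trace-to-events path: deconvolve, then threshold-call."""
    params = params or DeconvParams()
    s = deconvolve_trace(trace, params)
    noise = estimate_noise_sd(trace)
    return detect_transients(
        s,
        noise,
        params,
        start_time=trace.start_time,
        sampling_rate=trace.sampling_rate,
        neuron_id=trace.neuron_id,
    )


def count_events(train: EventTrain, window: Tuple[float, float]) -> int:
    """Number of events in the half-open window [t_a, t_b)."""
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ParameterError(f"zero-length or inverted window ({a}, {b})")
    lo, hi = np.searchsorted(train.event_times, [a, b], side="left")
    return int(hi - lo)


def transient_frequency(train: EventTrain, window: Tuple[float, float]) -> float:
    """Event rate in the window, events per minute."""
    a, b = float(window[0]), float(window[1])
    n = count_events(train, window)
    return n / (b - a) * 60.0
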