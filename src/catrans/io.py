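"""CSV / JSON readers and writers for the package's table schemas.

Schemas:

* traces: wide CSV, column 1 ``time_s``, one column per neuron id;
* events: long CSV ``neuron_id,time_s``;
* occupancy: CSV ``time_s,chamber`` with chamber in {saline, cocaine};
* ground truth: CSV ``neuron_id,true_class,baseline_rate,multiplier``;
* labels: CSV ``neuron_id,method,phase,label,statistic,p_or_thresholds``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    CHAMBERS,
    ClassificationResult,
    EventTrain,
    FluorescenceTrace,
    FormatError,
    OccupancyTrack,
)

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_events_csv",
    "read_events_csv",
    "write_occupancy_csv",
    "read_occupancy_csv",
    "write_labels_csv",
    "write_json",
    "read_json",
]


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kw)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


def write_traces_csv(path, traces: Iterable[FluorescenceTrace]) -> None:
    traces = list(traces)
    if not traces:
        raise FormatError("no traces to write")
    t0 = traces[0]
    for tr in traces[1:]:
        if tr.n_frames != t0.n_frames or tr.start_time != t0.start_time or tr.sampling_rate != t0.sampling_rate:
            raise FormatError("all traces must share one time grid to be written wide")
    df = pd.DataFrame({"time_s": t0.times()})
    for tr in traces:
        df[str(tr.neuron_id)] = tr.values
    df.to_csv(path, index=False, float_format="%.6g")


def read_traces_csv(path) -> List[FluorescenceTrace]:
    df = _read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: expected a time_s column plus neuron columns")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise FormatError(f"{path}: time_s is not uniformly sampled")
    rate = 1.0 / dt.mean()
    out = []
    for col in df.columns:
        if col == "time_s":
            continue
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise FormatError(f"{path}: non-finite value for neuron {col} at row {bad}")
        out.append(FluorescenceTrace(neuron_id=str(col), start_time=float(t[0]),
                                     sampling_rate=float(rate), values=vals))
    return out


def write_events_csv(path, trains: Iterable[EventTrain]) -> None:
    rows = []
    spans = {}
    for tr in trains:
        spans[str(tr.neuron_id)] = tr.span
        for t in tr.event_times:
            rows.append((str(tr.neuron_id), float(t)))
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    df.to_csv(path, index=False, float_format="%.6f")
    # span sidecar keeps zero-event neurons and the session extent recoverable
    side = Path(str(path)).with_suffix(".span.json")
    side.write_text(json.dumps({k: list(v) for k, v in spans.items()}, indent=1))


def read_events_csv(path, span: Optional[Tuple[float, float]] = None) -> List[EventTrain]:
    df = _read_csv(path, dtype={"neuron_id": str})
    for col in ("neuron_id", "time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    spans: Dict[str, Tuple[float, float]] = {}
    side = Path(str(path)).with_suffix(".span.json")
    if side.exists():
        spans = {k: (float(v[0]), float(v[1])) for k, v in json.loads(side.read_text()).items()}
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        row = int(times.index[times.isna()][0])
        raise FormatError(f"{path}: non-numeric time_s at row {row}")
    out = []
    ids = spans.keys() if spans else df["neuron_id"].unique()
    for nid in ids:
        ev = np.sort(times[df["neuron_id"] == nid].to_numpy(dtype=float))
        sp = span or spans.get(str(nid))
        if sp is None:
            lo = float(ev[0]) if ev.size else 0.0
            hi = float(ev[-1]) + 1.0 if ev.size else 1.0
            sp = (lo, hi)
        out.append(EventTrain(neuron_id=str(nid), event_times=ev, span=sp))
    return out


def write_occupancy_csv(path, track: OccupancyTrack) -> None:
    pd.DataFrame({"time_s": track.times, "chamber": track.chambers}).to_csv(
        path, index=False, float_format="%.3f"
    )


def read_occupancy_csv(path, session_end: Optional[float] = None) -> OccupancyTrack:
    df = _read_csv(path, dtype={"chamber": str})
    for col in ("time_s", "chamber"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = ~df["chamber"].isin(CHAMBERS)
    if bad.any():
        row = int(df.index[bad][0])
        raise FormatError(f"{path}: unknown chamber {df['chamber'][row]!r} at row {row}")
    return OccupancyTrack(
        times=df["time_s"].to_numpy(dtype=float),
        chambers=df["chamber"].to_numpy(dtype=object),
        session_end=session_end,
    )


def _p_or_thresholds(r: ClassificationResult) -> str:
    if r.p_value is not None:
        return f"p={r.p_value:.6g}"
    if r.null_low is not None and r.null_high is not None:
        return f"[{r.null_low:.6g},{r.null_high:.6g}]"
    return ""


def write_labels_csv(path, results: Iterable[ClassificationResult]) -> None:
    rows = [
        {
            "neuron_id": r.neuron_id,
            "method": r.method,
            "phase": r.phase or "",
            "label": r.label,
            "statistic": "" if r.statistic is None else r.statistic,
            "p_or_thresholds": _p_or_thresholds(r),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["neuron_id", "method", "phase", "label",
                                "statistic", "p_or_thresholds"]).to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(str(path)).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")


def read_json(path):
    try:
        return json.loads(Path(str(path)).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
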