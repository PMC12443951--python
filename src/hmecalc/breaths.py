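"""Per-breath reduction of raw flow/humidity traces.

Raw records are ~10 Hz samples of signed flow (l/min) and absolute
humidity (mg/l) taken at the moisture-benefit (P2) or water-output
(P4) position.  This module segments them into breaths, integrates
each breath to a volume and a flow-weighted mean concentration, and
selects the steady-state window.

The mean concentration is *flow-weighted*, integral(c |q| dt) /
integral(|q| dt), not time-weighted: the target quantity is
transported water mass per transported volume, and samples taken while
no gas moves carry no mass.  Integration is trapezoidal at the native
sampling; traces are never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .psychrometry import GasConditions, CABINET, volume_to_moles

__all__ = [
    "BreathTrace",
    "BreathSummary",
    "TraceError",
    "DegenerateBreathError",
    "NoSteadyStateError",
    "segment_breaths",
    "breath_summary",
    "summarize_trace",
    "select_steady_state",
    "read_trace_csv",
    "write_trace_csv",
]

#: Default flow hysteresis threshold for breath detection, l/min.
HYSTERESIS_THRESHOLD = 0.5
#: Shortest flow burst accepted as a breath, s.
MIN_BREATH_DURATION = 0.5
#: Sub-threshold dropouts shorter than this are bridged, s.
MAX_GAP_DURATION = 0.3

_TRACE_COLUMNS = ("time_s", "flow_l_min", "humidity_mg_l")


class TraceError(ValueError):
    """Malformed trace (time not increasing, excessive jitter, ...)."""


class DegenerateBreathError(ValueError):
    """Interval integrates to zero transported volume."""


class NoSteadyStateError(RuntimeError):
    """No steady window found in the per-breath summaries."""


@dataclass(frozen=True)
class BreathTrace:
    """A raw sensor record at one measuring position.

    ``flow`` is signed (l/min; zero while the valves route gas through
    the other limb), ``humidity`` is absolute (mg/l).  Time must be
    strictly increasing with approximately constant sampling (<= 5%
    jitter).
    """

    position: str  # "P2" or "P4"
    time: np.ndarray
    flow: np.ndarray
    humidity: np.ndarray
    conditions: GasConditions = CABINET

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        h = np.asarray(self.humidity, dtype=float)
        if not (t.shape == q.shape == h.shape) or t.ndim != 1:
            raise TraceError("time, flow and humidity must be equal-length 1-D arrays")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise TraceError("time must be strictly increasing")
            med = float(np.median(dt))
            if np.any(np.abs(dt - med) > 0.05 * med + 1e-12):
                raise TraceError("sample interval jitter exceeds 5%")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", q)
        object.__setattr__(self, "humidity", h)

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "flow_l_min": self.flow, "humidity_mg_l": self.humidity}
        )


@dataclass(frozen=True)
class BreathSummary:
    """Integrals of one breath: volume and flow-weighted mean humidity."""

    breath_index: int
    volume_l: float
    volume_mol: float
    mean_concentration_mg_l: float
    start_time: float
    end_time: float
    steady: bool = False


def segment_breaths(
    trace: BreathTrace,
    threshold: float = HYSTERESIS_THRESHOLD,
    min_duration: float = MIN_BREATH_DURATION,
    max_gap: float = MAX_GAP_DURATION,
) -> List[Tuple[int, int]]:
    """Split a trace into per-breath sample intervals.

    A breath is a maximal run of samples with |flow| above the
    hysteresis threshold (entry at ``threshold``, exit at half of it);
    sub-threshold dropouts shorter than ``max_gap`` seconds are
    bridged and bursts shorter than ``min_duration`` discarded, so
    sensor noise near zero flow neither fragments nor invents breaths.
    Partial bursts touching either end of the record are dropped.

    Returns half-open index pairs (i0, i1) into the trace arrays.
    """
    q = np.abs(trace.flow)
    n = len(q)
    if n == 0:
        warnings.warn("empty trace: no breaths found", stacklevel=2)
        return []
    hi, lo = threshold, 0.5 * threshold
    active = np.zeros(n, dtype=bool)
    state = False
    for i in range(n):
        if not state and q[i] >= hi:
            state = True
        elif state and q[i] < lo:
            state = False
        active[i] = state

    dt = trace.sample_interval if n >= 2 else 0.0
    runs = _runs(active)
    # bridge short gaps between active runs
    merged: List[Tuple[int, int]] = []
    for i0, i1 in runs:
        if merged and (i0 - merged[-1][1]) * dt <= max_gap:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    # drop short bursts and partial leading/trailing cycles
    kept = [
        (i0, i1)
        for i0, i1 in merged
        if (i1 - i0) * dt >= min_duration and i0 > 0 and i1 < n
    ]
    # The threshold only locates breaths; the flow ramps continue below
    # it, so walk each boundary outward to the foot of the ramp (first
    # sample at <= 5% of the threshold) and include that near-zero
    # anchor sample.  Expansion never crosses the midpoint of the gap
    # to a neighbouring burst.
    floor = 0.05 * threshold
    out = []
    for k, (i0, i1) in enumerate(kept):
        left_lim = (kept[k - 1][1] + i0) // 2 if k else 0
        right_lim = (i1 + kept[k + 1][0]) // 2 if k + 1 < len(kept) else n
        lo, hi = i0, i1
        while lo - 1 >= left_lim and q[lo - 1] > floor:
            lo -= 1
        lo = max(lo - 1, left_lim, 0)
        while hi < right_lim and q[hi] > floor:
            hi += 1
        hi = min(hi + 1, right_lim, n)
        out.append((lo, hi))
    if not out:
        warnings.warn("no complete breath cycle found in trace", stacklevel=2)
    return out


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open (start, stop) index pairs of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2].tolist(), idx[1::2].tolist()))


def breath_summary(
    trace: BreathTrace,
    interval: Tuple[int, int],
    conditions: Optional[GasConditions] = None,
    breath_index: int = 0,
) -> BreathSummary:
    """Integrate one breath interval to volume and mean concentration.

    volume = trapezoidal integral of |flow| dt; mean concentration =
    integral(c |flow| dt) / integral(|flow| dt).
    """
    i0, i1 = interval
    if not (0 <= i0 < i1 <= len(trace.time)):
        raise TraceError(f"interval {interval} outside trace of length {len(trace.time)}")
    cond = conditions or trace.conditions
    t = trace.time[i0:i1]
    q = np.abs(trace.flow[i0:i1]) / 60.0  # l/s
    c = trace.humidity[i0:i1]
    volume_l = float(np.trapezoid(q, t))
    if volume_l <= 0:
        raise DegenerateBreathError("breath interval transports no volume")
    water = float(np.trapezoid(c * q, t))
    return BreathSummary(
        breath_index=breath_index,
        volume_l=volume_l,
        volume_mol=volume_to_moles(volume_l, cond),
        mean_concentration_mg_l=water / volume_l,
        start_time=float(t[0]),
        end_time=float(t[-1]),
    )


def summarize_trace(
    trace: BreathTrace,
    conditions: Optional[GasConditions] = None,
    threshold: float = HYSTERESIS_THRESHOLD,
) -> List[BreathSummary]:
    """Segment a trace and summarize every complete breath."""
    return [
        breath_summary(trace, iv, conditions, breath_index=k)
        for k, iv in enumerate(segment_breaths(trace, threshold=threshold))
    ]


@dataclass(frozen=True)
class SteadyStateSelection:
    """Mean +/- sd of concentration and volume over the steady window."""

    first_steady_index: int
    n_breaths: int
    concentration_mg_l: float
    concentration_sd: float
    volume_l: float
    volume_sd: float
    volume_mol: float


def select_steady_state(
    summaries: Sequence[BreathSummary],
    tolerance: float = 0.005,
    window: int = 5,
) -> SteadyStateSelection:
    """Average the steady tail of a summary sequence.

    The first index from which concentration and volume vary by less
    than ``tolerance`` (relative, max-min over ``window`` consecutive
    breaths) opens the steady window; everything from there on is
    averaged.  Raises :class:`NoSteadyStateError`, reporting the drift,
    when no such window exists.
    """
    if len(summaries) < window:
        raise TraceError(
            f"need at least {window} breath summaries, got {len(summaries)}"
        )
    conc = np.array([s.mean_concentration_mg_l for s in summaries])
    vol = np.array([s.volume_l for s in summaries])
    first = _first_steady_index(np.vstack([conc, vol]), tolerance, window)
    if first is None:
        drift = max(_window_spread(conc), _window_spread(vol))
        raise NoSteadyStateError(
            f"no steady window of {window} breaths at tolerance {tolerance:.2%}; "
            f"residual drift {drift:.2%}"
        )
    c_tail, v_tail = conc[first:], vol[first:]
    cond = summaries[0]
    mean_vol = float(np.mean(v_tail))
    return SteadyStateSelection(
        first_steady_index=first,
        n_breaths=len(c_tail),
        concentration_mg_l=float(np.mean(c_tail)),
        concentration_sd=float(np.std(c_tail, ddof=1)) if len(c_tail) > 1 else 0.0,
        volume_l=mean_vol,
        volume_sd=float(np.std(v_tail, ddof=1)) if len(v_tail) > 1 else 0.0,
        volume_mol=cond.volume_mol / cond.volume_l * mean_vol,
    )


def _first_steady_index(series: np.ndarray, tolerance: float, window: int):
    """First index whose length-``window`` lookahead is flat in every row."""
    n = series.shape[1]
    for i in range(n - window + 1):
        ok = True
        for row in series:
            w = row[i : i + window]
            mean = abs(float(np.mean(w)))
            spread = float(np.max(w) - np.min(w))
            if spread > tolerance * max(mean, 1e-300):
                ok = False
                break
        if ok:
            return i
    return None


def _window_spread(row: np.ndarray) -> float:
    mean = abs(float(np.mean(row)))
    return float(np.max(row) - np.min(row)) / max(mean, 1e-300)


# ---------------------------------------------------------------------------
# Trace CSV I/O
# ---------------------------------------------------------------------------


def read_trace_csv(
    path,
    position: str,
    conditions: GasConditions = CABINET,
    dialect: str = "standard",
) -> BreathTrace:
    """Read a trace CSV (columns time_s, flow_l_min, humidity_mg_l).

    ``dialect='standard'`` expects comma separator with dot decimals;
    ``dialect='semicolon'`` accepts semicolon-separated, comma-decimal
    exports common on German-locale loggers.
    """
    if dialect == "standard":
        df = pd.read_csv(path)
    elif dialect == "semicolon":
        df = pd.read_csv(path, sep=";", decimal=",")
    else:
        raise ValueError(f"unknown CSV dialect {dialect!r}")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"trace file {path} lacks columns {missing}")
    return BreathTrace(
        position=position,
        time=df["time_s"].to_numpy(float),
        flow=df["flow_l_min"].to_numpy(float),
        humidity=df["humidity_mg_l"].to_numpy(float),
        conditions=conditions,
    )


def write_trace_csv(trace: BreathTrace, path) -> None:
    """Write a trace in the standard dialect with fixed 6-decimal floats."""
    with open(path, "w", newline="") as fh:
        fh.write(",".join(_TRACE_COLUMNS) + "\n")
        for t, q, h in zip(trace.time, trace.flow, trace.humidity):
            fh.write(f"{t:.6f},{q:.6f},{h:.6f}\n")
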