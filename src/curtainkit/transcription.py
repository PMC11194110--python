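"""Transcription-trajectory analysis: velocity, event classes, statistics.

A transcribing polymerase tracked along the DNA yields a position-time
trace measured in bp downstream of its promoter.  Traces are classified
as *snapback* (a single-interval upstream jump of at least 0.5 kb),
*early stop* (permanent termination within the first 10 kb) or
*continuous* (everything else), following the thresholds used for
single-molecule T7 transcription assays.  Processive fractions carry
Clopper-Pearson binomial confidence intervals, and the Fisher exact test
compares event counts between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TranscriptionTrace",
    "EventCall",
    "transcription_velocity",
    "classify_event",
    "processive_fraction",
    "fisher_exact_2x2",
    "EARLY_STOP_LIMIT_BP",
    "SNAPBACK_JUMP_BP",
]

EARLY_STOP_LIMIT_BP = 10_000.0   # termination strictly below this is an early stop
SNAPBACK_JUMP_BP = 500.0         # single-interval upstream jump at/above this


@dataclass
class TranscriptionTrace:
    times: np.ndarray               # s
    positions: np.ndarray           # bp downstream of the promoter
    promoter_bp: float = 0.0
    trace_id: str = "trace"
    dna_id: str = "dna"
    end_reason: str = "unknown"     # stall | unbinding | bleach | recording_end | unknown

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.positions < 0):
            raise ValueError("positions must be >= 0 (downstream of promoter)")


@dataclass
class EventCall:
    event_class: str                # continuous | early_stop | snapback
    velocity: float | None          # bp/s; None when no sustained motion
    stop_position: float            # bp, final position of the trace
    trace_id: str = "trace"
    dna_id: str = "dna"


def _onset_index(pos: np.ndarray, advance_tol: float) -> int | None:
    """First frame opening >= 3 consecutive advancing intervals."""
    adv = np.diff(pos) > advance_tol
    run = 0
    for i, a in enumerate(adv):
        run = run + 1 if a else 0
        if run >= 3:
            return i - 2
    return None


def _permanent_stop_index(
    times: np.ndarray, pos: np.ndarray, stop_tol: float, min_dwell: float
) -> int | None:
    """Index after which no net forward motion beyond ``stop_tol`` occurs
    for the remainder of the recording, lasting at least ``min_dwell`` s."""
    n = pos.size
    run_max = np.maximum.accumulate(pos[::-1])[::-1]  # max of pos[i:]
    for i in range(n):
        if run_max[i] <= pos[i] + stop_tol:
            if times[-1] - times[i] >= min_dwell:
                return i
            return None
    return None


def transcription_velocity(
    trace: TranscriptionTrace,
    advance_tol: float = 0.0,
    stop_tol: float = 100.0,
    min_dwell: float = 30.0,
) -> float | None:
    """Net transcription velocity (bp/s) from motion onset to terminus.

    Onset is the first frame of sustained forward motion (>= 3 consecutive
    advancing intervals); the terminus is the start of a permanent stall
    when one exists, otherwise the final frame.  Returns None (no-velocity
    flag) when no sustained motion is found.
    """
    pos, times = trace.positions, trace.times
    if pos.size < 5:
        raise ValueError(f"trace {trace.trace_id!r} too short ({pos.size} < 5 frames)")
    onset = _onset_index(pos, advance_tol)
    if onset is None:
        return None
    stop = _permanent_stop_index(times, pos, stop_tol, min_dwell)
    term = stop if stop is not None and stop > onset else pos.size - 1
    if term - onset < 4:
        return None
    dt = times[term] - times[onset]
    if dt <= 0:
        return None
    return float((pos[term] - pos[onset]) / dt)


def classify_event(
    trace: TranscriptionTrace,
    substrate_len: float | None = None,
    stop_tol: float = 100.0,
    min_dwell: float = 30.0,
) -> EventCall:
    """Classify a transcription trace.

    Priority: snapback (any single-interval upstream displacement
    >= 0.5 kb), then early stop (permanent termination strictly below
    10 kb), else continuous.
    """
    pos, times = trace.positions, trace.times
    vel = None
    if pos.size >= 5:
        vel = transcription_velocity(trace, stop_tol=stop_tol, min_dwell=min_dwell)
    jumps = -np.diff(pos) if pos.size > 1 else np.array([])
    if jumps.size and np.max(jumps) >= SNAPBACK_JUMP_BP:
        cls = "snapback"
    else:
        stop = _permanent_stop_index(times, pos, stop_tol, min_dwell)
        if stop is not None and pos[stop] < EARLY_STOP_LIMIT_BP:
            cls = "early_stop"
        else:
            cls = "continuous"
    return EventCall(
        event_class=cls,
        velocity=vel,
        stop_position=float(pos[-1]),
        trace_id=trace.trace_id,
        dna_id=trace.dna_id,
    )


def processive_fraction(
    calls: list[EventCall] | dict[str, list[EventCall]],
    alpha: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Fraction of continuously transcribing polymerases per group, with a
    Clopper-Pearson (1 - alpha) binomial confidence interval.

    ``calls`` may be a flat list (group "all") or a mapping such as
    {"single": [...], "multiple": [...]} for DNA molecules carrying one
    versus several transcription events.
    """
    groups = {"all": calls} if isinstance(calls, list) else dict(calls)
    out: dict[str, dict[str, float]] = {}
    for name, group in groups.items():
        if len(group) == 0:
            raise ValueError(f"group {name!r} is empty")
        k = sum(1 for c in group if c.event_class == "continuous")
        n = len(group)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        out[name] = {
            "fraction": k / n,
            "ci_low": float(lo),
            "ci_high": float(hi),
            "n": n,
            "n_continuous": k,
        }
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table
    (with a small relative tolerance against floating-point ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    p = float(np.sum(pmf[pmf <= p_obs * (1 + 1e-9)]))
    return min(p, 1.0)
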