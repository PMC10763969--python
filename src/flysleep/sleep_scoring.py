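"""Sleep-bout scoring, sleep-architecture metrics and transition propensities.

Sleep in the fly is operationally defined as a maximal run of 5 or more
consecutive minutes with zero beam crossings.  On top of that rule this module
computes per-phase (day/night, 12:12 LD) architecture summaries — total sleep,
bout number, mean bout length, waking activity — and the two-state Markov
transition propensities P(Doze) (active minute followed by an inactive one)
and P(Wake) (inactive followed by active), which separate sleep *pressure*
and sleep *depth* from sleep amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import MINUTES_PER_DAY, ActivityTrace

__all__ = [
    "SleepBout",
    "SleepMetrics",
    "TransitionProbs",
    "DEFAULT_MIN_BOUT",
    "phase_of_minute",
    "score_sleep",
    "sleep_mask",
    "sleep_metrics",
    "transition_probs",
    "hourly_transition_profile",
]

DEFAULT_MIN_BOUT = 5
PHASES = ("day", "night")

Phase = Literal["day", "night"]


def phase_of_minute(zt_min: int) -> Phase:
    """Phase of an absolute ZT-anchored minute under a 12:12 LD cycle.

    Day is ZT0–ZT12, i.e. ``(zt_min mod 1440) < 720`` (half-open, so minute
    719 is day and minute 720 is night).
    """
    if zt_min < 0:
        raise ValueError("zt_min must be >= 0")
    return "day" if (zt_min % MINUTES_PER_DAY) < 720 else "night"


@dataclass(frozen=True)
class SleepBout:
    """One maximal immobility run of at least the minimum bout length.

    ``start_min`` is absolute (ZT-anchored).  Truncation flags mark runs
    clipped by a recording edge, which are still counted as bouts but remain
    auditable.
    """

    fly_id: str
    start_min: int
    duration_min: int
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def end_min(self) -> int:
        """One past the bout's last minute (half-open)."""
        return self.start_min + self.duration_min


@dataclass
class SleepMetrics:
    """Per-fly, per-phase sleep architecture summary.

    Undefined quantities (no bouts; no waking minutes) are ``None`` rather
    than 0 so they never bias group means.
    """

    fly_id: str
    phase: Phase
    total_sleep_min: int
    bout_number: int
    mean_bout_len_min: float | None
    waking_activity: float | None


@dataclass
class TransitionProbs:
    """Per-fly conditional transition frequencies for one phase.

    ``p_doze``  = #(active t, inactive t+1) / #(active t)
    ``p_wake``  = #(inactive t, active t+1) / #(inactive t)

    over all minute pairs (t, t+1) with minute t in the phase; a zero
    denominator leaves the corresponding probability ``None``.
    """

    fly_id: str
    phase: Phase
    p_doze: float | None
    p_wake: float | None
    n_active_transitions: int
    n_inactive_transitions: int


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, length) pairs, by boundary detection."""
    inactive = np.asarray(counts) == 0
    if not inactive.any():
        return []
    padded = np.concatenate(([False], inactive, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def score_sleep(
    trace: ActivityTrace, min_bout: int = DEFAULT_MIN_BOUT
) -> list[SleepBout]:
    """Score sleep bouts: maximal zero-count runs of >= ``min_bout`` minutes.

    Runs touching either recording edge are returned with truncation flags
    set.  Bout start times are absolute (trace index + ZT anchor).
    """
    if min_bout < 1:
        raise ValueError("min_bout must be >= 1")
    n = len(trace)
    bouts = []
    for start, length in _zero_runs(trace.counts):
        if length < min_bout:
            continue
        bouts.append(
            SleepBout(
                fly_id=trace.fly_id,
                start_min=start + trace.zt0_offset_min,
                duration_min=length,
                truncated_start=start == 0,
                truncated_end=start + length == n,
            )
        )
    return bouts


def sleep_mask(trace: ActivityTrace, bouts: Sequence[SleepBout]) -> np.ndarray:
    """Boolean per-minute mask (trace-indexed), True inside any sleep bout."""
    mask = np.zeros(len(trace), dtype=bool)
    for b in bouts:
        lo = b.start_min - trace.zt0_offset_min
        mask[lo : lo + b.duration_min] = True
    return mask


def sleep_metrics(
    trace: ActivityTrace, bouts: Sequence[SleepBout]
) -> dict[Phase, SleepMetrics]:
    """Day and night architecture summaries from a trace and its scored bouts.

    Bout minutes are assigned to phases by overlap — a bout spanning the
    lights-off boundary contributes its day minutes to day totals and its
    night minutes to night totals, and is counted in ``bout_number`` of every
    phase it intersects.  ``mean_bout_len_min`` is the per-phase sleep total
    over the per-phase bout count.  Waking activity is total beam crosses in
    the phase's waking minutes divided by the number of those minutes.
    """
    n = len(trace)
    zt = np.arange(n) + trace.zt0_offset_min
    is_day = (zt % MINUTES_PER_DAY) < 720
    asleep = sleep_mask(trace, bouts)
    out: dict[Phase, SleepMetrics] = {}
    for phase in PHASES:
        in_phase = is_day if phase == "day" else ~is_day
        total_sleep = int((asleep & in_phase).sum())
        n_bouts = 0
        for b in bouts:
            lo = b.start_min - trace.zt0_offset_min
            if in_phase[lo : lo + b.duration_min].any():
                n_bouts += 1
        waking = in_phase & ~asleep
        n_waking = int(waking.sum())
        out[phase] = SleepMetrics(
            fly_id=trace.fly_id,
            phase=phase,
            total_sleep_min=total_sleep,
            bout_number=n_bouts,
            mean_bout_len_min=total_sleep / n_bouts if n_bouts else None,
            waking_activity=(
                float(trace.counts[waking].sum() / n_waking) if n_waking else None
            ),
        )
    return out


def _transition_counts(
    trace: ActivityTrace, phase: Phase
) -> tuple[int, int, int, int]:
    """(doze events, active origins, wake events, inactive origins) for a phase."""
    active = trace.active
    if len(trace) < 2:
        raise ValueError("trace must have at least 2 minutes")
    zt = np.arange(len(trace) - 1) + trace.zt0_offset_min
    is_day = (zt % MINUTES_PER_DAY) < 720
    sel = is_day if phase == "day" else ~is_day
    a_t = active[:-1][sel]
    a_t1 = active[1:][sel]
    n_active = int(a_t.sum())
    n_inactive = int((~a_t).sum())
    n_doze = int((a_t & ~a_t1).sum())
    n_wake = int((~a_t & a_t1).sum())
    return n_doze, n_active, n_wake, n_inactive


def transition_probs(trace: ActivityTrace, phase: Phase) -> TransitionProbs:
    """P(Doze) and P(Wake) for one fly in one phase.

    Each minute pair (t, t+1) is assigned to the phase of minute t (the final
    minute of the trace is never an origin).  Undefined ratios are ``None``.
    """
    n_doze, n_active, n_wake, n_inactive = _transition_counts(trace, phase)
    return TransitionProbs(
        fly_id=trace.fly_id,
        phase=phase,
        p_doze=n_doze / n_active if n_active else None,
        p_wake=n_wake / n_inactive if n_inactive else None,
        n_active_transitions=n_active,
        n_inactive_transitions=n_inactive,
    )


def hourly_transition_profile(traces: Iterable[ActivityTrace]) -> pd.DataFrame:
    """Mean P(Doze)/P(Wake) per ZT hour across flies, with dispersion.

    Minute pairs are binned by the ZT hour of the origin minute t; each fly
    contributes one ratio per hour (when defined), and ratios are then
    summarized across flies.  Hours with no defined value for any fly carry
    NaN.

    Returns a 24-row DataFrame indexed by ``zt_hour`` with columns
    ``p_doze_mean``, ``p_doze_sem``, ``n_flies_doze`` and the ``p_wake``
    equivalents.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("at least one trace required")
    per_fly_doze: list[np.ndarray] = []
    per_fly_wake: list[np.ndarray] = []
    for trace in traces:
        active = trace.active
        zt = np.arange(len(trace) - 1) + trace.zt0_offset_min
        hour = (zt % MINUTES_PER_DAY) // 60
        doze = np.full(24, np.nan)
        wake = np.full(24, np.nan)
        for h in range(24):
            sel = hour == h
            a_t, a_t1 = active[:-1][sel], active[1:][sel]
            n_act = int(a_t.sum())
            n_inact = int((~a_t).sum())
            if n_act:
                doze[h] = (a_t & ~a_t1).sum() / n_act
            if n_inact:
                wake[h] = (~a_t & a_t1).sum() / n_inact
        per_fly_doze.append(doze)
        per_fly_wake.append(wake)
    dz = np.vstack(per_fly_doze)
    wk = np.vstack(per_fly_wake)

    def _summ(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        valid = ~np.isnan(m)
        n = valid.sum(axis=0)
        filled = np.where(valid, m, 0.0)
        mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
        dev2 = np.where(valid, (filled - np.where(n > 0, mean, 0.0)) ** 2, 0.0)
        var = np.where(n > 1, dev2.sum(axis=0) / np.maximum(n - 1, 1), np.nan)
        sem = np.sqrt(var / np.maximum(n, 1))
        return mean, sem, n

    dz_mean, dz_sem, dz_n = _summ(dz)
    wk_mean, wk_sem, wk_n = _summ(wk)
    return pd.DataFrame(
        {
            "p_doze_mean": dz_mean,
            "p_doze_sem": dz_sem,
            "n_flies_doze": dz_n,
            "p_wake_mean": wk_mean,
            "p_wake_sem": wk_sem,
            "n_flies_wake": wk_n,
        },
        index=pd.RangeIndex(24, name="zt_hour"),
    )
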