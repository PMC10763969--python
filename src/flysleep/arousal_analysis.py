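"""Arousal-threshold and reactivity scoring from mechanical-stimulus assays.

Two assay designs are supported, both delivered hourly starting at ZT0:

* **escalating** — vibration intensities rise from 0 to a maximum (default
  1.2 g) in fixed steps; the arousal threshold of a sleeping fly is the first
  intensity that evokes movement within a short window (default 15 s),
  reported as a proportion of the maximum force.
* **fixed** — a single maximal stimulus; *reactivity* is whether a sleeping
  fly moves within a longer window (default 60 s), analyzed as a function of
  how long the fly had been asleep, both binned and by per-trial linear
  regression.

A fly counts as asleep at a stimulus when the immobility run ending at the
stimulus minute is at least 5 minutes long (the same rule the sleep scorer
uses, applied causally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ActivityTrace, StimulusEvent
from .regression_stats import AncovaResult, RegressionResult, ancova, ols_fit
from .sleep_scoring import DEFAULT_MIN_BOUT, Phase, phase_of_minute

__all__ = [
    "ArousalRecord",
    "ReactivityBin",
    "time_asleep_at",
    "threshold_from_assay",
    "mean_threshold",
    "reactivity_table",
    "reactivity_curve",
    "reactivity_regression",
    "reactivity_ancova",
]

DEFAULT_MAX_G = 1.2
DEFAULT_AROUSAL_WINDOW_S = 15.0
DEFAULT_REACTIVITY_WINDOW_S = 60.0


@dataclass
class ArousalRecord:
    """Outcome of one escalating-intensity assay on one fly.

    ``threshold_prop`` is the responding intensity over the protocol maximum
    (so 0.25, 0.5, 0.75 or 1.0 under the default 4-level series); it is
    present only when the fly was asleep and responded at some level.  A
    sleeping fly that never responded is ``censored``.
    """

    fly_id: str
    zt_min: int
    asleep_at_stimulus: bool
    time_asleep_min: int | None = None
    threshold_prop: float | None = None
    censored: bool = False

    @property
    def phase(self) -> Phase:
        return phase_of_minute(self.zt_min)


@dataclass
class ReactivityBin:
    """Fraction of sleeping-fly trials responding, per prior-time-asleep bin.

    ``phase`` is "day"/"night", or "all" when trials were pooled.
    """

    phase: str
    bin_lo_min: float
    bin_hi_min: float
    n_trials: int
    n_responded: int

    @property
    def reactivity_pct(self) -> float | None:
        if self.n_trials == 0:
            return None
        return 100.0 * self.n_responded / self.n_trials


def time_asleep_at(
    trace: ActivityTrace, t: int, min_bout: int = DEFAULT_MIN_BOUT
) -> int | None:
    """Minutes of sleep immediately preceding trace minute ``t``.

    Returns the length k of the maximal zero-count run ending at minute t−1
    if k >= ``min_bout``, else ``None`` (the fly is awake by the sleep rule).
    """
    n = len(trace)
    if not 0 <= t < n:
        raise ValueError(f"t={t} outside trace of length {n}")
    k = 0
    counts = trace.counts
    i = t - 1
    while i >= 0 and counts[i] == 0:
        k += 1
        i -= 1
    return k if k >= min_bout else None


def threshold_from_assay(
    events: Sequence[StimulusEvent],
    trace: ActivityTrace,
    max_intensity_g: float = DEFAULT_MAX_G,
    response_window_s: float = DEFAULT_AROUSAL_WINDOW_S,
    min_bout: int = DEFAULT_MIN_BOUT,
) -> ArousalRecord:
    """Score one escalating assay into an :class:`ArousalRecord`.

    The threshold is the first intensity with a response inside the window,
    as a proportion of ``max_intensity_g``.  A 0 g delivery is a sham level:
    a response to it marks spontaneous waking and can never define a
    threshold.  Output is invariant to events after the first response.
    """
    if not events:
        raise ValueError("assay has no events")
    fly_ids = {e.fly_id for e in events}
    if len(fly_ids) > 1:
        raise ValueError("assay events span multiple flies")
    events = sorted(events, key=lambda e: e.intensity_g)
    intensities = [e.intensity_g for e in events]
    if any(b <= a for a, b in zip(intensities, intensities[1:])):
        raise ValueError("escalating assay requires strictly increasing intensities")
    assay_min = min(e.zt_min for e in events)
    t = assay_min - trace.zt0_offset_min
    asleep_for = time_asleep_at(trace, t, min_bout=min_bout)
    if asleep_for is None:
        return ArousalRecord(
            fly_id=events[0].fly_id, zt_min=assay_min, asleep_at_stimulus=False
        )
    for e in events:
        if (
            e.intensity_g > 0
            and e.responded
            and e.latency_s is not None
            and e.latency_s <= response_window_s
        ):
            return ArousalRecord(
                fly_id=e.fly_id,
                zt_min=assay_min,
                asleep_at_stimulus=True,
                time_asleep_min=asleep_for,
                threshold_prop=e.intensity_g / max_intensity_g,
            )
    return ArousalRecord(
        fly_id=events[0].fly_id,
        zt_min=assay_min,
        asleep_at_stimulus=True,
        time_asleep_min=asleep_for,
        censored=True,
    )


def mean_threshold(
    records: Iterable[ArousalRecord],
    phase: Phase,
    censored_policy: str = "exclude",
) -> pd.DataFrame:
    """Per-fly mean arousal threshold for one phase, with dispersion.

    Only sleeping assays enter.  Censored assays (no response at any level)
    are excluded by default; ``censored_policy="assign_max"`` instead scores
    them at threshold 1.0.  Flies with no eligible assay get NaN means; the
    censored fraction is always reported.

    Returns a DataFrame with one row per fly: ``mean_threshold``,
    ``sd_threshold``, ``n_assays``, ``n_censored``, ``censored_fraction``.
    """
    if censored_policy not in ("exclude", "assign_max"):
        raise ValueError("censored_policy must be 'exclude' or 'assign_max'")
    rows: dict[str, list[ArousalRecord]] = {}
    for r in records:
        if r.asleep_at_stimulus and r.phase == phase:
            rows.setdefault(r.fly_id, []).append(r)
    out = []
    for fly_id, recs in sorted(rows.items()):
        vals = [r.threshold_prop for r in recs if r.threshold_prop is not None]
        n_cens = sum(r.censored for r in recs)
        if censored_policy == "assign_max":
            vals = vals + [1.0] * n_cens
        arr = np.array(vals, dtype=float)
        out.append(
            {
                "fly_id": fly_id,
                "phase": phase,
                "mean_threshold": float(arr.mean()) if arr.size else np.nan,
                "sd_threshold": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
                "n_assays": len(recs),
                "n_censored": n_cens,
                "censored_fraction": n_cens / len(recs),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "fly_id",
            "phase",
            "mean_threshold",
            "sd_threshold",
            "n_assays",
            "n_censored",
            "censored_fraction",
        ],
    )


def reactivity_table(
    events: Iterable[StimulusEvent],
    traces: Mapping[str, ActivityTrace] | Sequence[ActivityTrace],
    response_window_s: float = DEFAULT_REACTIVITY_WINDOW_S,
    min_bout: int = DEFAULT_MIN_BOUT,
) -> pd.DataFrame:
    """Per-trial reactivity records from fixed-intensity stimuli.

    Keeps only trials delivered to a sleeping fly; ``responded`` is movement
    within ``response_window_s`` of delivery.  Returns a DataFrame with
    columns ``fly_id``, ``zt_min``, ``phase``, ``time_asleep_min``,
    ``responded``.
    """
    if not isinstance(traces, Mapping):
        traces = {t.fly_id: t for t in traces}
    rows = []
    for e in events:
        if e.protocol != "fixed":
            raise ValueError("reactivity_table expects fixed-protocol events")
        trace = traces[e.fly_id]
        t = e.zt_min - trace.zt0_offset_min
        asleep_for = time_asleep_at(trace, t, min_bout=min_bout)
        if asleep_for is None:
            continue
        rows.append(
            {
                "fly_id": e.fly_id,
                "zt_min": e.zt_min,
                "phase": phase_of_minute(e.zt_min),
                "time_asleep_min": asleep_for,
                "responded": bool(
                    e.responded
                    and e.latency_s is not None
                    and e.latency_s <= response_window_s
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["fly_id", "zt_min", "phase", "time_asleep_min", "responded"]
    )


def reactivity_curve(
    table: pd.DataFrame,
    bin_width: int = 5,
    t_lo: int = 5,
    t_hi: int = 40,
    phase: Phase | None = None,
) -> list[ReactivityBin]:
    """Bin per-trial reactivity by prior time asleep.

    Half-open bins [t_lo, t_lo+w), … up to t_hi, plus a final overflow bin
    [t_hi, ∞).  Empty bins are retained with ``n_trials = 0`` and an
    undefined percentage.
    """
    if table.empty:
        raise ValueError("reactivity table is empty")
    if phase is not None:
        table = table[table["phase"] == phase]
    edges = list(range(t_lo, t_hi + 1, bin_width))
    bins: list[ReactivityBin] = []
    spans = [(float(a), float(b)) for a, b in zip(edges, edges[1:])]
    spans.append((float(t_hi), np.inf))
    ts = table["time_asleep_min"].to_numpy()
    resp = table["responded"].to_numpy(dtype=bool)
    for lo, hi in spans:
        sel = (ts >= lo) & (ts < hi)
        bins.append(
            ReactivityBin(
                phase=phase if phase is not None else "all",
                bin_lo_min=lo,
                bin_hi_min=hi,
                n_trials=int(sel.sum()),
                n_responded=int(resp[sel].sum()),
            )
        )
    return bins


def reactivity_regression(
    table: pd.DataFrame, phase: Phase | None = None
) -> RegressionResult:
    """OLS of per-trial response (0/100) on prior time asleep.

    Trial-level 0/100 outcomes are the default observational unit (matching
    regressions whose denominator degrees of freedom count trials).
    """
    if phase is not None:
        table = table[table["phase"] == phase]
    x = table["time_asleep_min"].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct time-asleep values")
    y = table["responded"].to_numpy(dtype=bool).astype(float) * 100.0
    return ols_fit(x, y)


def reactivity_ancova(
    tables: Mapping[str, pd.DataFrame], phase: Phase | None = None
) -> AncovaResult:
    """Compare reactivity-vs-time-asleep lines across genotypes (ANCOVA)."""
    groups = []
    for _, table in sorted(tables.items()):
        if phase is not None:
            table = table[table["phase"] == phase]
        x = table["time_asleep_min"].to_numpy(dtype=float)
        y = table["responded"].to_numpy(dtype=bool).astype(float) * 100.0
        groups.append((x, y))
    return ancova(groups)
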