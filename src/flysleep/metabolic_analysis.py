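"""Sleep-bout-aligned indirect calorimetry: state means and metabolic downscaling.

CO2 production is recorded in 5-minute bins while activity is monitored
simultaneously, so every bin can be classified as *sleep* (all of its minutes
inside one scored sleep bout), *wake* (no minute inside a bout) or *mixed*.

The downscaling statistic follows the printed per-bout recipe: within one
sleep bout with successive bin values v1, v2, …, the percent change at bin k
is

    Δ_k = (v1 − vk) / v1 × 100

so positive Δ means metabolic suppression relative to the start of the bout.
Δ_k values are averaged across a fly's bouts per phase and regressed on time
asleep; genotype contrasts use the ANCOVA machinery in
:mod:`flysleep.regression_stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MetabolicTrace
from .regression_stats import AncovaResult, RegressionResult, ancova, ols_fit
from .sleep_scoring import Phase, SleepBout, phase_of_minute

__all__ = [
    "BoutVCO2Profile",
    "StateMeans",
    "classify_bins",
    "pct_change",
    "bout_profile",
    "fly_pct_change_by_time",
    "state_means",
    "metabolic_regression",
]


@dataclass
class BoutVCO2Profile:
    """Per-bout VCO2 bins and percent change relative to the first bin.

    ``v_bins[0]`` covers the bout's first 5 minutes; ``pct_change[k]`` is
    Δ_{k+2}, one entry shorter than ``v_bins``.  ``pct_change`` is ``None``
    (flagged) when the first bin is zero.
    """

    fly_id: str
    start_min: int
    duration_min: int
    phase: Phase
    v_bins: np.ndarray
    pct_change: np.ndarray | None


@dataclass
class StateMeans:
    """Mean per-bin VCO2 by behavioral state for one fly and phase."""

    fly_id: str
    phase: Phase
    vco2_wake: float | None
    vco2_sleep: float | None
    vco2_total: float | None


def classify_bins(
    bouts: Sequence[SleepBout], mtrace: MetabolicTrace
) -> np.ndarray:
    """Label every calorimetry bin "sleep", "wake" or "mixed".

    A bin is sleep iff all of its minutes lie inside one sleep bout, wake iff
    none does, and mixed otherwise.  Bouts and trace must share the fly and
    the ZT anchor (bouts are absolute-time; the trace's first bin starts at
    its ``zt0_offset_min``).
    """
    for b in bouts:
        if b.fly_id != mtrace.fly_id:
            raise ValueError(
                f"bout fly {b.fly_id!r} does not match trace fly {mtrace.fly_id!r}"
            )
    n_bins = len(mtrace)
    w = mtrace.bin_min
    n_min = n_bins * w
    asleep = np.zeros(n_min, dtype=bool)
    for b in bouts:
        lo = b.start_min - mtrace.zt0_offset_min
        hi = lo + b.duration_min
        if lo < 0 or hi > n_min:
            # bouts may legitimately overhang the calorimetry window edge
            lo, hi = max(lo, 0), min(hi, n_min)
        asleep[lo:hi] = True
    per_bin = asleep.reshape(n_bins, w)
    labels = np.where(
        per_bin.all(axis=1), "sleep", np.where(~per_bin.any(axis=1), "wake", "mixed")
    )
    return labels


def pct_change(v1: float, vk: float) -> float:
    """Percent change of bin k relative to the bout's first bin.

    ``(v1 − vk) / v1 × 100``: positive when vk < v1 (suppression).  Returns
    NaN (flagged undefined) when v1 <= 0.
    """
    if vk < 0:
        raise ValueError("vk must be >= 0")
    if v1 <= 0:
        return math.nan
    return (v1 - vk) / v1 * 100.0


def bout_profile(
    bout: SleepBout,
    mtrace: MetabolicTrace,
    allow_offset_min: int = 0,
) -> BoutVCO2Profile | None:
    """VCO2 profile of one sleep bout, or ``None`` if it cannot be aligned.

    Bins are counted from the bout's own start; the stream is never
    re-binned.  By default only bouts starting exactly on the instrument's
    bin grid are profiled.  ``allow_offset_min`` tolerates a start up to that
    many minutes past a grid line, in which case the profile begins at the
    first full grid bin inside the bout.  Bouts shorter than one bin (after
    any shift) are excluded.
    """
    w = mtrace.bin_min
    rel_start = bout.start_min - mtrace.zt0_offset_min
    misalign = rel_start % w
    shift = 0 if misalign == 0 else w - misalign
    if (misalign and misalign > allow_offset_min) or rel_start < 0:
        return None
    first_bin = (rel_start + shift) // w
    usable = bout.duration_min - shift
    n_full = usable // w
    if n_full < 1:
        return None
    last_bin = first_bin + n_full
    if last_bin > len(mtrace):
        n_full = len(mtrace) - first_bin
        if n_full < 1:
            return None
        last_bin = first_bin + n_full
    v_bins = mtrace.vco2[first_bin:last_bin].copy()
    v1 = v_bins[0]
    if v1 > 0:
        deltas = np.array([pct_change(v1, vk) for vk in v_bins[1:]])
    else:
        deltas = None
    return BoutVCO2Profile(
        fly_id=bout.fly_id,
        start_min=bout.start_min,
        duration_min=bout.duration_min,
        phase=phase_of_minute(bout.start_min),
        v_bins=v_bins,
        pct_change=deltas,
    )


def fly_pct_change_by_time(
    profiles: Iterable[BoutVCO2Profile], phase: Phase
) -> pd.DataFrame:
    """Average Δ_k across one fly's bouts at each time-asleep point.

    Δ_k (bin k vs bin 1) is attributed to time asleep 5·k minutes (10, 15,
    20, … min); at each point the mean runs over all bouts of the phase long
    enough to contain bin k.  Returns columns ``fly_id``, ``phase``,
    ``time_asleep_min``, ``mean_pct_change``, ``n_bouts``.
    """
    by_time: dict[int, list[float]] = {}
    fly_ids = set()
    profiles = [p for p in profiles if p.phase == phase and p.pct_change is not None]
    for p in profiles:
        fly_ids.add(p.fly_id)
        for j, delta in enumerate(p.pct_change):
            k = j + 2  # pct_change[0] is bin 2 vs bin 1
            by_time.setdefault(k * 5, []).append(float(delta))
    if len(fly_ids) > 1:
        raise ValueError("profiles span multiple flies; aggregate per fly")
    fly_id = fly_ids.pop() if fly_ids else ""
    rows = [
        {
            "fly_id": fly_id,
            "phase": phase,
            "time_asleep_min": t,
            "mean_pct_change": float(np.mean(vals)),
            "n_bouts": len(vals),
        }
        for t, vals in sorted(by_time.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["fly_id", "phase", "time_asleep_min", "mean_pct_change", "n_bouts"],
    )


def state_means(
    labels: np.ndarray, mtrace: MetabolicTrace, phase: Phase
) -> StateMeans:
    """Mean VCO2 per bin over sleep and wake bins of one phase.

    Mixed bins are excluded from the state means (they would dilute the
    contrast) but included in ``vco2_total``.  A state with no bins in the
    phase is flagged ``None``.
    """
    n_bins = len(mtrace)
    if labels.shape != (n_bins,):
        raise ValueError("labels and trace disagree on bin count")
    start_zt = np.arange(n_bins) * mtrace.bin_min + mtrace.zt0_offset_min
    is_day = (start_zt % 1440) < 720
    in_phase = is_day if phase == "day" else ~is_day
    v = mtrace.vco2

    def _mean(sel: np.ndarray) -> float | None:
        return float(v[sel].mean()) if sel.any() else None

    return StateMeans(
        fly_id=mtrace.fly_id,
        phase=phase,
        vco2_wake=_mean(in_phase & (labels == "wake")),
        vco2_sleep=_mean(in_phase & (labels == "sleep")),
        vco2_total=_mean(in_phase),
    )


def metabolic_regression(
    points_by_genotype: Mapping[str, pd.DataFrame],
    max_time_asleep_min: float | None = 40.0,
) -> tuple[dict[str, RegressionResult], AncovaResult | None]:
    """Per-genotype OLS of mean Δ on time asleep, plus cross-genotype ANCOVA.

    ``points_by_genotype`` maps genotype to a DataFrame with columns
    ``time_asleep_min`` and ``mean_pct_change`` (typically the concatenation
    of per-fly tables from :func:`fly_pct_change_by_time`).  By default the
    fit is restricted to points up to 40 minutes of sleep — the early-bout
    regime where the decline is near-linear and points are well replicated;
    long bouts are rare, so later points are sparse, high-leverage and (once
    suppression bottoms out) flatten the line.  Pass ``None`` to fit the full
    range.  The ANCOVA slot is ``None`` with a single genotype.
    """
    fits: dict[str, RegressionResult] = {}
    groups = []
    for genotype, df in sorted(points_by_genotype.items()):
        if max_time_asleep_min is not None:
            df = df[df["time_asleep_min"] <= max_time_asleep_min]
        x = df["time_asleep_min"].to_numpy(dtype=float)
        y = df["mean_pct_change"].to_numpy(dtype=float)
        if np.unique(x).size < 3:
            raise ValueError(f"genotype {genotype!r}: need >= 3 distinct time values")
        fits[genotype] = ols_fit(x, y)
        groups.append((x, y))
    anc = ancova(groups) if len(groups) >= 2 else None
    return fits, anc
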