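"""Synthetic fly cohorts with known ground truth for every pipeline stage.

The generative model mirrors the measurement chain end to end:

* **Activity** — a per-minute two-state (active/inactive) Markov chain with
  phase-dependent switch probabilities (``p_doze``: active→inactive,
  ``p_wake``: inactive→active).  Active minutes emit zero-truncated Poisson
  beam-cross counts, inactive minutes emit 0, so the scorer's activity
  dichotomy is exact.  The chain is simulated run-by-run with geometric dwell
  times, resampled at phase boundaries (exact by memorylessness).
* **Arousal** — at each hourly stimulus on a fly asleep for t minutes, the
  response probability at intensity s is logistic((s − θ(t))/σ) with
  θ(t) = theta0 + beta_theta·t; a rising θ models deepening sleep, a flat θ
  models shallow sleep throughout the bout.
* **Metabolism** — per-minute CO2 rate is ``v_wake/5`` awake and
  ``v_sleep0/5 · max(1 − delta·t, floor)`` when asleep for t minutes, summed
  into 5-minute bins and multiplied by mean-one lognormal noise.

Two documented parameter presets, ``control_like`` and ``nf1_like``, emulate
the qualitative genotype contrasts (fragmented shallow sleep, flat arousal
threshold, absent metabolic downscaling, elevated CO2 output in the
mutant-like preset).  All preset numbers are invented emulations chosen for
testability, not measured values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_formats import (
    MINUTES_PER_DAY,
    N_CHANNELS,
    ActivityTrace,
    MetabolicTrace,
    StimulusEvent,
    write_dam_monitor,
    write_stimulus_log,
    write_vco2_table,
)
from .sleep_scoring import DEFAULT_MIN_BOUT

__all__ = [
    "FlyParams",
    "StimulusProtocol",
    "CohortConfig",
    "escalating_protocol",
    "fixed_protocol",
    "simulate_activity",
    "emit_counts",
    "simulate_stimuli",
    "simulate_assay_cohort",
    "simulate_vco2",
    "genotype_presets",
    "simulate_cohort",
]


@dataclass(frozen=True)
class FlyParams:
    """Generative parameters of one genotype.

    Probabilities are per-minute; ``theta0`` (g) and ``beta_theta`` (g per
    minute asleep) shape the arousal threshold; ``sigma_resp`` (g) is the
    logistic response scale; VCO2 parameters are per 5-minute bin in
    arbitrary consistent units; ``delta`` is the proportional per-minute
    decline of the sleeping rate, floored at ``floor_frac`` of ``v_sleep0``;
    ``cv_noise`` is the coefficient of variation of multiplicative lognormal
    bin noise.
    """

    p_doze_day: float
    p_doze_night: float
    p_wake_day: float
    p_wake_night: float
    lambda_active: float
    theta0: float
    beta_theta: float
    sigma_resp: float
    v_wake: float
    v_sleep0: float
    delta: float
    cv_noise: float
    floor_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_doze_day", "p_doze_night", "p_wake_day", "p_wake_night"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lambda_active <= 0:
            raise ValueError("lambda_active must be > 0")
        if self.sigma_resp <= 0:
            raise ValueError("sigma_resp must be > 0")
        if self.beta_theta < 0:
            raise ValueError("beta_theta must be >= 0")
        if not 0 < self.v_sleep0 <= self.v_wake:
            raise ValueError("need 0 < v_sleep0 <= v_wake")
        if self.delta < 0 or self.cv_noise < 0:
            raise ValueError("delta and cv_noise must be >= 0")
        if not 0 <= self.floor_frac <= 1:
            raise ValueError("floor_frac must lie in [0, 1]")

    def p_doze(self, is_day: bool) -> float:
        return self.p_doze_day if is_day else self.p_doze_night

    def p_wake(self, is_day: bool) -> float:
        return self.p_wake_day if is_day else self.p_wake_night

    def theta(self, time_asleep_min: float) -> float:
        return self.theta0 + self.beta_theta * time_asleep_min


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus schedule and response windows of one assay design."""

    kind: str  # "escalating" | "fixed"
    levels: tuple[float, ...]
    max_g: float
    response_window_s: float
    assay_interval_min: int = 60

    def __post_init__(self) -> None:
        if self.kind not in ("escalating", "fixed"):
            raise ValueError("kind must be 'escalating' or 'fixed'")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if max(self.levels) > self.max_g:
            raise ValueError("levels exceed max_g")


def escalating_protocol(
    max_g: float = 1.2, step_g: float = 0.3, response_window_s: float = 15.0
) -> StimulusProtocol:
    """0 → max in fixed steps (the 0 g delivery is a sham level)."""
    n = round(max_g / step_g)
    levels = tuple(round(step_g * k, 10) for k in range(0, n + 1))
    return StimulusProtocol(
        kind="escalating",
        levels=levels,
        max_g=max_g,
        response_window_s=response_window_s,
    )


def fixed_protocol(
    max_g: float = 1.2, response_window_s: float = 60.0
) -> StimulusProtocol:
    """A single maximal stimulus per assay (reactivity design)."""
    return StimulusProtocol(
        kind="fixed", levels=(max_g,), max_g=max_g,
        response_window_s=response_window_s,
    )


# ---------------------------------------------------------------------------
# activity


def _simulate_states(
    params: FlyParams, n_min: int, zt0_offset_min: int, rng: np.random.Generator
) -> np.ndarray:
    """Latent minute states (True = active), initial state active.

    Dwell times within a phase are geometric; a dwell crossing a phase
    boundary is truncated there and resampled under the new phase's switch
    probability, which reproduces the per-minute chain exactly.
    """
    states = np.empty(n_min, dtype=bool)
    m = 0
    active = True
    while m < n_min:
        zt = m + zt0_offset_min
        is_day = (zt % MINUTES_PER_DAY) < 720
        p = params.p_doze(is_day) if active else params.p_wake(is_day)
        # trace index of the next phase boundary
        into_phase = zt % 720
        boundary = m + (720 - into_phase)
        block_end = min(boundary, n_min)
        if p <= 0:
            states[m:block_end] = active
            m = block_end
            continue
        dwell = int(rng.geometric(p))
        if m + dwell <= block_end:
            states[m : m + dwell] = active
            m += dwell
            active = not active
        else:
            states[m:block_end] = active
            m = block_end
    return states


def emit_counts(
    states: np.ndarray, params: FlyParams, rng: np.random.Generator
) -> np.ndarray:
    """Beam-cross counts: zero-truncated Poisson when active, 0 when inactive."""
    counts = np.zeros(states.size, dtype=np.int64)
    idx = np.flatnonzero(states)
    draws = rng.poisson(params.lambda_active, idx.size)
    while True:
        zero = draws == 0
        if not zero.any():
            break
        draws[zero] = rng.poisson(params.lambda_active, int(zero.sum()))
    counts[idx] = draws
    return counts


def simulate_activity(
    params: FlyParams,
    days: int = 1,
    seed: int | np.random.Generator | None = None,
    zt0_offset_min: int = 0,
    fly_id: str = "sim",
    genotype: str = "",
) -> tuple[ActivityTrace, np.ndarray]:
    """Simulate one fly's activity trace; also return the latent minute states."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_min = days * MINUTES_PER_DAY
    states = _simulate_states(params, n_min, zt0_offset_min, rng)
    trace = ActivityTrace(
        fly_id=fly_id,
        counts=emit_counts(states, params, rng),
        zt0_offset_min=zt0_offset_min,
        genotype=genotype,
    )
    return trace, states


# ---------------------------------------------------------------------------
# stimuli


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700.0, 700.0)))


def _time_inactive_before(states: np.ndarray, t: int) -> int:
    k = 0
    i = t - 1
    while i >= 0 and not states[i]:
        k += 1
        i -= 1
    return k


def simulate_stimuli(
    states: np.ndarray,
    params: FlyParams,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator | None = None,
    zt0_offset_min: int = 0,
    fly_id: str = "sim",
    feedback: bool = True,
    min_bout: int = DEFAULT_MIN_BOUT,
) -> tuple[list[StimulusEvent], np.ndarray]:
    """Deliver the protocol's assays against a latent state chain.

    Assays run every ``assay_interval_min`` starting at ZT0.  At each level
    the fly responds with probability logistic((s − θ(t))/σ), where t is its
    current time asleep (θ(theta0) for an awake fly); an escalating series
    stops at the first response.  Response latencies are uniform on the
    response window.  With ``feedback`` (default) a responding fly's assay
    minute is set active in the returned state copy, so later assays see the
    interrupted bout; the input array is never modified.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    work = states.copy()
    events: list[StimulusEvent] = []
    n = states.size
    first_assay = (-zt0_offset_min) % protocol.assay_interval_min
    for t in range(first_assay, n, protocol.assay_interval_min):
        if t == 0:
            continue  # no history yet; a fly cannot be scored asleep
        k = _time_inactive_before(work, t)
        asleep = k >= min_bout
        theta = params.theta(k) if asleep else params.theta0
        zt_min = t + zt0_offset_min
        responded_assay = False
        for s in protocol.levels:
            p = _logistic((s - theta) / params.sigma_resp)
            responded = bool(rng.random() < p)
            latency = (
                float(rng.uniform(0.0, protocol.response_window_s))
                if responded
                else None
            )
            events.append(
                StimulusEvent(
                    fly_id=fly_id,
                    zt_min=zt_min,
                    protocol=protocol.kind,
                    intensity_g=s,
                    responded=responded,
                    latency_s=latency,
                )
            )
            if responded:
                responded_assay = True
                break  # escalating series stops; fixed has one level anyway
        if responded_assay and feedback:
            work[t] = True
    return events, work


def simulate_assay_cohort(
    params: FlyParams,
    protocol: StimulusProtocol,
    n_flies: int,
    days: int = 1,
    seed: int = 0,
    prefix: str = "f",
) -> tuple[dict[str, ActivityTrace], list[StimulusEvent]]:
    """Simulate a stimulus experiment on ``n_flies`` independent flies.

    Each fly's monitor trace is emitted from its post-stimulus states, so the
    stimulus log and the activity record tell one coherent story (a responder
    shows movement at the assay minute).  Returns traces keyed by fly id plus
    the pooled event list.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    traces: dict[str, ActivityTrace] = {}
    events: list[StimulusEvent] = []
    n_min = days * MINUTES_PER_DAY
    for fi in range(n_flies):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(fi,))
        )
        fly_id = f"{prefix}{fi:03d}"
        states = _simulate_states(params, n_min, 0, rng)
        ev, work = simulate_stimuli(
            states, params, protocol, seed=rng, fly_id=fly_id
        )
        traces[fly_id] = ActivityTrace(
            fly_id=fly_id, counts=emit_counts(work, params, rng)
        )
        events.extend(ev)
    return traces, events


# ---------------------------------------------------------------------------
# metabolism


def simulate_vco2(
    states: np.ndarray,
    params: FlyParams,
    seed: int | np.random.Generator | None = None,
    bin_min: int = 5,
    zt0_offset_min: int = 0,
    fly_id: str = "sim",
) -> MetabolicTrace:
    """CO2-per-bin trace from latent states.

    Time-in-bout t counts completed inactive minutes (t = 0 on the first
    inactive minute).  Bin values are per-minute rates summed over the bin
    times mean-one lognormal noise with CV ``cv_noise``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = states.size
    idx = np.arange(n)
    last_active = np.maximum.accumulate(np.where(states, idx, -1))
    t_in_bout = idx - last_active - 1  # 0 on first inactive minute
    sleep_rate = (params.v_sleep0 / bin_min) * np.maximum(
        1.0 - params.delta * t_in_bout, params.floor_frac
    )
    rate = np.where(states, params.v_wake / bin_min, sleep_rate)
    n_bins = n // bin_min
    bins = rate[: n_bins * bin_min].reshape(n_bins, bin_min).sum(axis=1)
    if params.cv_noise > 0:
        sigma2 = np.log1p(params.cv_noise**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), n_bins)
        bins = bins * noise
    return MetabolicTrace(
        fly_id=fly_id, vco2=bins, bin_min=bin_min, zt0_offset_min=zt0_offset_min
    )


# ---------------------------------------------------------------------------
# presets and cohorts


def genotype_presets() -> dict[str, FlyParams]:
    """Invented control-like and mutant-like parameter sets.

    ``control_like`` sleeps consolidated at night, its arousal threshold
    rises with time asleep and its sleeping CO2 rate declines along the bout;
    ``nf1_like`` wakes more readily, is hyperactive, keeps a flat (and lower)
    arousal threshold, shows no metabolic downscaling, and produces more CO2
    in both states.
    """
    control = FlyParams(
        p_doze_day=0.06,
        p_doze_night=0.12,
        p_wake_day=0.10,
        p_wake_night=0.03,
        lambda_active=2.0,
        theta0=0.30,
        beta_theta=0.02,
        sigma_resp=0.30,
        v_wake=1.0,
        v_sleep0=0.80,
        delta=0.01,
        cv_noise=0.05,
    )
    nf1 = FlyParams(
        p_doze_day=0.04,
        p_doze_night=0.05,
        p_wake_day=0.15,
        p_wake_night=0.12,
        lambda_active=3.5,
        theta0=0.20,
        beta_theta=0.0,
        sigma_resp=0.30,
        v_wake=1.30,
        v_sleep0=1.10,
        delta=0.0,
        cv_noise=0.05,
    )
    return {"control_like": control, "nf1_like": nf1}


@dataclass
class CohortConfig:
    """Recipe for a complete on-disk synthetic experiment."""

    n_flies: int
    days: int = 1
    seed: int = 0
    genotypes: dict[str, FlyParams] = field(default_factory=genotype_presets)
    escalating: StimulusProtocol = field(default_factory=escalating_protocol)
    fixed: StimulusProtocol = field(default_factory=fixed_protocol)
    vco2_bin_min: int = 5

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not self.genotypes:
            raise ValueError("at least one genotype required")


def _fly_rng(seed: int, gi: int, fi: int, purpose: int) -> np.random.Generator:
    """Independent per-fly, per-purpose substream; adding flies never
    perturbs existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(gi, fi, purpose))
    )


def _write_monitors(
    traces: list[ActivityTrace], outdir: Path, prefix: str
) -> dict[str, str]:
    """Write traces into <=32-channel monitor files; returns old->new id map."""
    mapping: dict[str, str] = {}
    for part, lo in enumerate(range(0, len(traces), N_CHANNELS), start=1):
        chunk = traces[lo : lo + N_CHANNELS]
        path = outdir / f"{prefix}_{part:02d}.txt"
        write_dam_monitor(chunk, path, lights_on="00:00")
        for ch, t in enumerate(chunk, start=1):
            mapping[t.fly_id] = f"{path.stem}#ch{ch:02d}"
    return mapping


def simulate_cohort(config: CohortConfig, outdir: str | Path) -> dict[str, object]:
    """Generate and write a full synthetic experiment.

    Three independent sub-cohorts per genotype mirror the three instruments
    of the study design: a sleep/metabolism cohort (monitor files +
    ``vco2.csv``), an escalating-assay arousal cohort (its own monitor files
    + ``stimulus_escalating.csv``) and a fixed-assay reactivity cohort
    (monitor files + ``stimulus_fixed.csv``).  Ground truth goes to
    ``truth.csv`` (per-fly parameters) and ``truth_states.csv`` (latent
    minute states, '0'/'1' strings); the run recipe to ``config.yaml``.
    Outputs are byte-identical for identical seeds.

    Returns the in-memory objects keyed by experiment for direct use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    experiments = {"sleep": 0, "arousal": 2, "reactivity": 4}
    truth_rows: list[dict[str, object]] = []
    state_rows: list[tuple[str, str, str]] = []
    result: dict[str, object] = {"traces": {}, "states": {}}
    vco2_traces: list[MetabolicTrace] = []
    esc_events: list[StimulusEvent] = []
    fix_events: list[StimulusEvent] = []
    genotype_of: dict[str, str] = {}
    n_min = config.days * MINUTES_PER_DAY

    for gi, (gname, params) in enumerate(sorted(config.genotypes.items())):
        per_exp: dict[str, list[tuple[ActivityTrace, np.ndarray, list]]] = {
            e: [] for e in experiments
        }
        for fi in range(config.n_flies):
            fly_id = f"{gname}_f{fi:03d}"
            for exp, purpose in experiments.items():
                rng = _fly_rng(config.seed, gi, fi, purpose)
                states = _simulate_states(params, n_min, 0, rng)
                events: list[StimulusEvent] = []
                if exp == "arousal":
                    events, states = simulate_stimuli(
                        states, params, config.escalating,
                        seed=_fly_rng(config.seed, gi, fi, purpose + 1),
                        fly_id=fly_id,
                    )
                elif exp == "reactivity":
                    events, states = simulate_stimuli(
                        states, params, config.fixed,
                        seed=_fly_rng(config.seed, gi, fi, purpose + 1),
                        fly_id=fly_id,
                    )
                # monitor counts reflect any stimulus-evoked waking, so the
                # written trace and the stimulus log tell one coherent story
                trace = ActivityTrace(
                    fly_id=fly_id,
                    counts=emit_counts(states, params, rng),
                    genotype=gname,
                )
                per_exp[exp].append((trace, states, events))
        for exp in experiments:
            traces = [t for t, _, _ in per_exp[exp]]
            id_map = _write_monitors(traces, outdir, f"monitor_{exp}_{gname}")
            for fi, (trace, states, events) in enumerate(per_exp[exp]):
                new_id = id_map[trace.fly_id]
                trace.fly_id = new_id
                genotype_of[new_id] = gname
                state_rows.append(
                    (exp, new_id, "".join("1" if s else "0" for s in states))
                )
                row = {"experiment": exp, "fly_id": new_id, "genotype": gname}
                row.update(asdict(params))
                truth_rows.append(row)
                if exp == "sleep":
                    vco2_traces.append(
                        simulate_vco2(
                            states,
                            params,
                            seed=_fly_rng(config.seed, gi, fi, 1),
                            bin_min=config.vco2_bin_min,
                            fly_id=new_id,
                        )
                    )
                elif exp == "arousal":
                    esc_events.extend(
                        StimulusEvent(new_id, e.zt_min, e.protocol, e.intensity_g,
                                      e.responded, e.latency_s)
                        for e in events
                    )
                else:
                    fix_events.extend(
                        StimulusEvent(new_id, e.zt_min, e.protocol, e.intensity_g,
                                      e.responded, e.latency_s)
                        for e in events
                    )
            result["traces"].setdefault(exp, {}).update(
                {t.fly_id: t for t, _, _ in per_exp[exp]}
            )
            result["states"].setdefault(exp, {}).update(
                {t.fly_id: s for t, s, _ in per_exp[exp]}
            )

    write_vco2_table(vco2_traces, outdir / "vco2.csv")
    write_stimulus_log(esc_events, outdir / "stimulus_escalating.csv")
    write_stimulus_log(fix_events, outdir / "stimulus_fixed.csv")

    import csv as _csv

    with (outdir / "truth.csv").open("w", encoding="ascii", newline="") as fh:
        fieldnames = list(truth_rows[0].keys())
        writer = _csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(truth_rows)
    with (outdir / "truth_states.csv").open("w", encoding="ascii", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["experiment", "fly_id", "states"])
        writer.writerows(state_rows)
    cfg = {
        "n_flies": config.n_flies,
        "days": config.days,
        "seed": config.seed,
        "vco2_bin_min": config.vco2_bin_min,
        "genotypes": {g: asdict(p) for g, p in sorted(config.genotypes.items())},
        "escalating": asdict(config.escalating),
        "fixed": asdict(config.fixed),
    }
    with (outdir / "config.yaml").open("w", encoding="ascii") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    result.update(
        {
            "vco2": {t.fly_id: t for t in vco2_traces},
            "escalating_events": esc_events,
            "fixed_events": fix_events,
            "genotype_of": genotype_of,
        }
    )
    return result
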