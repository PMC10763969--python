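"""Generator determinism, degenerate limits, and generative/estimator closure."""

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from flysleep import (
    CohortConfig,
    FlyParams,
    escalating_protocol,
    fixed_protocol,
    genotype_presets,
    read_dam_monitor,
    read_stimulus_log,
    read_vco2_table,
    score_sleep,
    simulate_activity,
    simulate_cohort,
    simulate_stimuli,
    simulate_vco2,
    transition_probs,
)
from flysleep.synthetic_cohort import _fly_rng


BASE = FlyParams(
    p_doze_day=0.06, p_doze_night=0.12, p_wake_day=0.10, p_wake_night=0.03,
    lambda_active=2.0, theta0=0.3, beta_theta=0.02, sigma_resp=0.3,
    v_wake=1.0, v_sleep0=0.8, delta=0.01, cv_noise=0.05,
)


class TestSimulateActivity:
    def test_zero_doze_never_sleeps(self):
        params = replace(BASE, p_doze_day=0.0, p_doze_night=0.0)
        trace, states = simulate_activity(params, seed=1)
        assert states.all()
        assert score_sleep(trace) == []

    def test_absorbing_sleep_single_bout(self):
        params = replace(BASE, p_doze_day=1.0, p_doze_night=1.0,
                         p_wake_day=0.0, p_wake_night=0.0)
        trace, states = simulate_activity(params, seed=1)
        assert states[0] and not states[1:].any()
        (bout,) = score_sleep(trace)
        assert (bout.start_min, bout.duration_min) == (1, 1439)

    def test_active_minutes_have_positive_counts(self):
        trace, states = simulate_activity(BASE, seed=2)
        assert (trace.counts[states] > 0).all()
        assert (trace.counts[~states] == 0).all()

    def test_determinism(self):
        t1, s1 = simulate_activity(BASE, seed=7)
        t2, s2 = simulate_activity(BASE, seed=7)
        assert np.array_equal(t1.counts, t2.counts)
        assert np.array_equal(s1, s2)

    def test_invalid_probability_errors(self):
        with pytest.raises(ValueError):
            replace(BASE, p_wake_day=1.5)

    def test_stationary_occupancy(self):
        # long-run fraction of active minutes ~ p_wake / (p_wake + p_doze)
        params = replace(BASE, p_doze_day=0.05, p_doze_night=0.05,
                         p_wake_day=0.10, p_wake_night=0.10)
        active = np.concatenate(
            [simulate_activity(params, days=10, seed=100 + i)[1]
             for i in range(10)]
        )
        expected = 0.10 / 0.15
        assert abs(active.mean() - expected) < 0.02

    def test_estimator_recovery_closes_loop(self):
        params = replace(BASE, p_doze_day=0.05, p_doze_night=0.05,
                         p_wake_day=0.10, p_wake_night=0.10)
        n_doze = n_act = n_wake = n_inact = 0
        for i in range(40):
            trace, _ = simulate_activity(params, seed=200 + i)
            for phase in ("day", "night"):
                tp = transition_probs(trace, phase)
                n_doze += tp.p_doze * tp.n_active_transitions
                n_act += tp.n_active_transitions
                n_wake += tp.p_wake * tp.n_inactive_transitions
                n_inact += tp.n_inactive_transitions
        assert abs(n_doze / n_act - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_act)
        assert abs(n_wake / n_inact - 0.10) < 3 * np.sqrt(0.10 * 0.90 / n_inact)


class TestSimulateStimuli:
    def test_deterministic_limit_threshold_is_lowest_level(self):
        # theta far below the lowest nonzero level, tiny response scale:
        # the fly always responds at 0.3 g, never at the 0 g sham
        params = replace(BASE, theta0=0.29, beta_theta=0.0, sigma_resp=1e-4)
        states = np.zeros(1440, dtype=bool)
        states[0] = True
        events, _ = simulate_stimuli(states, params, escalating_protocol(),
                                     seed=3, fly_id="f")
        by_assay: dict[int, list] = {}
        for e in events:
            by_assay.setdefault(e.zt_min, []).append(e)
        for zt, ev in by_assay.items():
            responded = [e for e in ev if e.responded]
            assert len(responded) == 1
            assert responded[0].intensity_g == pytest.approx(0.3)

    def test_latencies_within_window(self):
        events, _ = simulate_stimuli(
            np.zeros(1440, dtype=bool), BASE, fixed_protocol(), seed=4, fly_id="f"
        )
        for e in events:
            if e.responded:
                assert 0 <= e.latency_s <= 60.0

    def test_feedback_wakes_responders(self):
        params = replace(BASE, theta0=0.0, sigma_resp=1e-4)  # always responds
        states = np.zeros(1440, dtype=bool)
        states[0] = True
        _, work = simulate_stimuli(states, params, fixed_protocol(), seed=5)
        assay_minutes = np.arange(60, 1440, 60)
        assert work[assay_minutes].all()
        untouched = np.ones(1440, dtype=bool)
        untouched[assay_minutes] = False
        assert not work[untouched & (np.arange(1440) > 0)].any()

    def test_no_feedback_leaves_states_alone(self):
        params = replace(BASE, theta0=0.0, sigma_resp=1e-4)
        states = np.zeros(1440, dtype=bool)
        _, work = simulate_stimuli(states, params, fixed_protocol(), seed=6,
                                   feedback=False)
        assert not work.any()

    def test_escalating_threshold_matches_enumeration_oracle(self):
        # fly asleep k minutes at each assay; expected threshold from the
        # closed sum over the 4 levels P(first response at level j)
        params = replace(BASE, theta0=0.3, beta_theta=0.0, sigma_resp=0.3)
        states = np.zeros(1440, dtype=bool)
        states[0] = True
        protocol = escalating_protocol()
        levels = [s for s in protocol.levels if s > 0]
        p_resp = [1 / (1 + np.exp(-(s - 0.3) / 0.3)) for s in levels]
        # oracle: enumerate outcomes of the escalating series
        expected, reach = 0.0, 1.0
        p_any = 0.0
        for s, p in zip(levels, p_resp):
            expected += reach * p * (s / 1.2)
            p_any += reach * p
            reach *= 1 - p
        expected /= p_any  # conditional on responding at some level
        draws = []
        for i in range(400):
            events, _ = simulate_stimuli(states, params, protocol, seed=700 + i,
                                         feedback=False, fly_id="f")
            for e in events:
                if e.responded and e.intensity_g > 0:
                    draws.append(e.intensity_g / 1.2)
        draws = np.array(draws)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se


class TestSimulateVco2:
    def test_all_asleep_no_decline_constant_bins(self):
        params = replace(BASE, delta=0.0, cv_noise=0.0)
        states = np.zeros(60, dtype=bool)
        mt = simulate_vco2(states, params, seed=1)
        assert np.allclose(mt.vco2, params.v_sleep0)

    def test_all_awake_constant_bins(self):
        params = replace(BASE, cv_noise=0.0)
        mt = simulate_vco2(np.ones(60, dtype=bool), params, seed=1)
        assert np.allclose(mt.vco2, params.v_wake)

    def test_decline_follows_programmed_rate(self):
        params = replace(BASE, delta=0.01, cv_noise=0.0)
        states = np.zeros(100, dtype=bool)
        mt = simulate_vco2(states, params, seed=1)
        # bin k sums minutes 5k..5k+4 with factors 1 - delta * t
        for k in range(3):
            t = np.arange(5 * k, 5 * k + 5)
            expected = params.v_sleep0 / 5 * np.maximum(1 - 0.01 * t, 0.5).sum()
            assert mt.vco2[k] == pytest.approx(expected)

    def test_floor_caps_decline(self):
        params = replace(BASE, delta=0.1, cv_noise=0.0, floor_frac=0.5)
        states = np.zeros(200, dtype=bool)
        mt = simulate_vco2(states, params, seed=1)
        assert mt.vco2[-1] == pytest.approx(params.v_sleep0 * 0.5)

    def test_noise_is_mean_one(self):
        params = replace(BASE, delta=0.0, cv_noise=0.2)
        states = np.zeros(1440 * 40, dtype=bool)
        mt = simulate_vco2(states, params, seed=9)
        assert abs(mt.vco2.mean() / params.v_sleep0 - 1.0) < 0.01


class TestPresetsAndCohort:
    def test_preset_directions(self):
        presets = genotype_presets()
        control, nf1 = presets["control_like"], presets["nf1_like"]
        assert nf1.p_wake_night > control.p_wake_night
        assert nf1.lambda_active > control.lambda_active
        assert nf1.beta_theta == 0.0 and control.beta_theta > 0
        assert nf1.delta == 0.0 and control.delta > 0
        assert nf1.v_wake > control.v_wake and nf1.v_sleep0 > control.v_sleep0

    def test_preset_night_sleep_direction(self):
        presets = genotype_presets()
        means = {}
        for name, params in presets.items():
            totals = []
            for i in range(15):
                trace, _ = simulate_activity(params, seed=4000 + i)
                bouts = score_sleep(trace)
                from flysleep import sleep_metrics

                totals.append(sleep_metrics(trace, bouts)["night"].total_sleep_min)
            means[name] = np.mean(totals)
        assert means["nf1_like"] < means["control_like"]

    def test_zero_flies_errors(self):
        with pytest.raises(ValueError):
            CohortConfig(n_flies=0)

    def test_cohort_determinism_and_files(self, tmp_path):
        config = CohortConfig(n_flies=3, days=1, seed=11)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(config, out1)
        simulate_cohort(config, out2)
        files = sorted(p.name for p in out1.iterdir())
        assert files == sorted(p.name for p in out2.iterdir())
        for name in files:
            h1 = hashlib.sha256((out1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((out2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name
        expected = {
            "vco2.csv", "stimulus_escalating.csv", "stimulus_fixed.csv",
            "truth.csv", "truth_states.csv", "config.yaml",
        }
        assert expected <= set(files)

    def test_adding_a_fly_does_not_perturb_existing_streams(self):
        a = _fly_rng(5, 0, 0, 0).integers(0, 1000, 10)
        b = _fly_rng(5, 0, 0, 0).integers(0, 1000, 10)
        c = _fly_rng(5, 0, 1, 0).integers(0, 1000, 10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_cohort_end_to_end_smoke(self, tmp_path):
        from flysleep import (
            reactivity_table,
            sleep_metrics,
            threshold_from_assay,
        )

        config = CohortConfig(n_flies=4, days=1, seed=21)
        outdir = tmp_path / "cohort"
        simulate_cohort(config, outdir)
        # read everything back through the io layer and run each stage
        vco2 = {t.fly_id: t for t in read_vco2_table(outdir / "vco2.csv")}
        esc = read_stimulus_log(outdir / "stimulus_escalating.csv")
        fix = read_stimulus_log(outdir / "stimulus_fixed.csv")
        assert esc and fix and vco2
        monitors = {
            exp: {
                t.fly_id: t
                for p in sorted(outdir.glob(f"monitor_{exp}_*"))
                for t in read_dam_monitor(p)
            }
            for exp in ("sleep", "arousal", "reactivity")
        }
        assert len(monitors["sleep"]) == 8
        for t in monitors["sleep"].values():
            metrics = sleep_metrics(t, score_sleep(t))
            assert set(metrics) == {"day", "night"}
        assays: dict[tuple, list] = {}
        for e in esc:
            assays.setdefault((e.fly_id, e.zt_min), []).append(e)
        records = [
            threshold_from_assay(ev, monitors["arousal"][fly])
            for (fly, _), ev in assays.items()
            if fly in monitors["arousal"]
        ]
        assert any(r.asleep_at_stimulus for r in records)
        table = reactivity_table(
            [e for e in fix], monitors["reactivity"]
        )
        assert not table.empty
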