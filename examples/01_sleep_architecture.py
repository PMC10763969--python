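"""Score sleep bouts and per-phase architecture for one simulated fly.

Simulates a control-like fly for one day, applies the 5-min immobility rule,
and prints total sleep, bout number, mean bout length and waking activity
for day (ZT0-12) and night (ZT12-24).
"""

from flysleep import genotype_presets, score_sleep, simulate_activity, sleep_metrics

params = genotype_presets()["control_like"]
trace, _ = simulate_activity(params, days=1, seed=11, fly_id="demo")
bouts = score_sleep(trace)  # maximal zero-count runs of >= 5 min

print(f"{len(bouts)} sleep bouts; longest {max(b.duration_min for b in bouts)} min")
for phase, m in sleep_metrics(trace, bouts).items():
    print(
        f"{phase:>5}: {m.total_sleep_min:4d} min sleep in {m.bout_number:2d} bouts "
        f"(mean {m.mean_bout_len_min:5.1f} min), "
        f"waking activity {m.waking_activity:.2f} crosses/min"
    )
# Consolidated night sleep (long bouts, most of the 720 night minutes) and
# modest daytime sleep are the expected control-like pattern.
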