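"""Arousal thresholds from escalating-intensity assays, control vs mutant-like.

Hourly assays deliver 0 -> 1.2 g vibrations in 0.3 g steps; the threshold of
a sleeping fly is the first intensity that wakes it within 15 s, as a
proportion of 1.2 g.  The control-like threshold rises with time asleep
(deep sleep); the nf1-like one stays flat and low.
"""

import numpy as np

from flysleep import (
    escalating_protocol,
    genotype_presets,
    mean_threshold,
    simulate_assay_cohort,
    threshold_from_assay,
)

for name, params in sorted(genotype_presets().items()):
    traces, events = simulate_assay_cohort(
        params, escalating_protocol(), n_flies=20, seed=3
    )
    assays = {}
    for e in events:
        assays.setdefault((e.fly_id, e.zt_min), []).append(e)
    records = [threshold_from_assay(ev, traces[fly])
               for (fly, _), ev in assays.items()]
    asleep = [r for r in records if r.asleep_at_stimulus]
    print(f"{name}: {len(asleep)} sleeping assays of {len(records)}")
    for phase in ("day", "night"):
        df = mean_threshold(records, phase)
        print(f"  {phase:>5}: mean threshold "
              f"{np.nanmean(df['mean_threshold']):.3f} of max force, "
              f"censored fraction {df['censored_fraction'].mean():.2f}")
# Expect the control-like mean threshold to sit clearly above the nf1-like
# one in both phases (deeper sleep needs a stronger stimulus to break).
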