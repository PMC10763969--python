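"""Estimate P(Doze) and P(Wake) and recover the generator's inputs.

P(Doze) is the chance an active minute is followed by an inactive one (sleep
pressure); P(Wake) the reverse (shallowness of sleep).  Estimates pooled over
a simulated cohort should land on the programmed per-phase probabilities.
"""

import numpy as np

from flysleep import genotype_presets, hourly_transition_profile, simulate_activity, transition_probs

params = genotype_presets()["control_like"]
traces = [simulate_activity(params, days=2, seed=100 + i, fly_id=f"f{i}")[0]
          for i in range(25)]

for phase, true_doze, true_wake in [("day", 0.06, 0.10), ("night", 0.12, 0.03)]:
    doze = np.mean([transition_probs(t, phase).p_doze for t in traces])
    wake = np.mean([transition_probs(t, phase).p_wake for t in traces])
    print(f"{phase:>5}: P(Doze) {doze:.3f} (true {true_doze}), "
          f"P(Wake) {wake:.3f} (true {true_wake})")

profile = hourly_transition_profile(traces)
print("\nhourly P(Wake), ZT0-5:",
      np.round(profile["p_wake_mean"].to_numpy()[:6], 3))
# The hourly profile steps between the two phase values at ZT12/ZT24.
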