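"""Reactivity as a function of time asleep, with per-genotype regressions.

Reactivity is the fraction of sleeping flies that move within 60 s of a
maximal (1.2 g) stimulus.  In control-like flies it declines the longer the
fly has been asleep (rising arousal threshold); in nf1-like flies it stays
high.  Trials are per-fly 0/100 outcomes regressed on prior time asleep;
genotype lines are compared by ANCOVA.
"""

from flysleep import (
    fixed_protocol,
    genotype_presets,
    reactivity_ancova,
    reactivity_curve,
    reactivity_regression,
    reactivity_table,
    simulate_assay_cohort,
)

tables = {}
for name, params in sorted(genotype_presets().items()):
    traces, events = simulate_assay_cohort(
        params, fixed_protocol(), n_flies=40, seed=17
    )
    tables[name] = reactivity_table(events, traces)
    fit = reactivity_regression(tables[name])
    print(f"{name}: slope {fit.slope:+.3f} %/min asleep, "
          f"intercept {fit.intercept:.1f}%, p(slope=0) = {fit.p_slope:.2g}, "
          f"n = {fit.n} trials")
    for b in reactivity_curve(tables[name])[:3]:
        pct = "  --" if b.reactivity_pct is None else f"{b.reactivity_pct:4.0f}"
        print(f"   asleep [{b.bin_lo_min:.0f}, {b.bin_hi_min:.0f}) min: "
              f"{pct}% of {b.n_trials} trials reactive")

anc = reactivity_ancova(tables)
print(f"\nANCOVA slopes: F{anc.df_slopes} = {anc.f_slopes:.1f}, "
      f"p = {anc.p_slopes:.2g}")
# A clearly negative control-like slope against a flat nf1-like line is the
# shallow-sleep phenotype; the equal-slopes F-test picks up the difference.
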