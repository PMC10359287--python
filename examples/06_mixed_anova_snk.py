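"""Balanced mixed-model ANOVA of a community descriptor with SNK post-hoc.

With Reef random and nested in Time x Region, the expected mean squares put
Reef(T x R) in the denominator of every fixed-effect F; Cochran's C checks
variance homogeneity first, and SNK groups the factor levels.
"""

import seatherm as st

niches = st.default_niches()
samples, _ = st.simulate_community(niches, st.ScenarioSpec(delta_t=1.0, seed=42))
catalog = st.catalog_from_niches(niches)
table = st.descriptor_table(samples, catalog).reset_index()

anova = st.mixed_anova(table, "biomass_turf_g", transform="sqrt")
print(anova)

for factor in ("year", "region"):
    snk = st.snk_for_factor(table, "biomass_turf_g", factor, anova)
    print(f"\nSNK ({factor}): {snk.summary()}")

print("\nThe F for Time is MS_Time / MS_Reef(TxR) — reef-to-reef variation,")
print("not quadrat noise, is the right yardstick for the survey effects.")
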