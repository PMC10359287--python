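"""Univariate community descriptors per quadrat and per region x survey.

Richness counts taxa with positive biomass; Shannon H' (nats) and Pielou J'
are computed on biomass shares; group biomass splits the standing crop into
the four morpho-functional classes.
"""

import seatherm as st

niches = st.default_niches()
samples, _ = st.simulate_community(niches, st.ScenarioSpec(delta_t=1.0, seed=42))
catalog = st.catalog_from_niches(niches)

table = st.descriptor_table(samples, catalog)
summary = st.descriptor_summary(table)

cols = ["richness_mean", "shannon_mean", "biomass_g_mean", "biomass_turf_g_mean"]
print(summary[cols].round(2))
print("\nEach row is a region x survey mean over its 30 quadrats. Turf biomass")
print("rises between the surveys because the warm-affinity turf species sit")
print("closer to their optima after the +1 degC increment.")
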