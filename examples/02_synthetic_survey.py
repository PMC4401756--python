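"""Generate a synthetic multi-population ant-EFN-herbivore survey.

The default scenario mirrors a two-census field design: 10 populations x 30
plants, a 15-species ant pool with a size-recruitment trade-off, one
low-EFN/small-ant matched population, seven high-EFN/big-ant matched
populations (three of them designed evolutionary hotspots) and two
mismatched populations with sparse random ant assemblages.
"""

from antmosaic import ScenarioConfig, generate_survey, occupancy_stability

config = ScenarioConfig(seed=11)
survey = generate_survey(config)

for name, table in survey.tables.items():
    print(f"{name:24s} {len(table):5d} rows")

gt = survey.ground_truth.populations
print("\ndesigned labels:")
for pop, d in gt.items():
    tag = "hotspot" if d["hotspot"] else ("matched" if d["matched"] else "mismatched")
    print(f"  {pop}: {d['scenario']:14s} designed EFN mean {d['efn_mean']:5.1f}  -> {tag}")

st = occupancy_stability(survey.tables["plants"], survey.tables["ant_observations"])
print(
    f"\noccupancy stability: {st.prop_occupied_both:.0%} of plants ant-occupied in both censuses, "
    f"{st.prop_occupied_neither:.0%} in neither; among doubly occupied plants "
    f"{st.prop_same_species:.0%} kept the same ant species "
    "(the generator's 74% persistence plus re-draws that land on the same species)"
)

# survey.write("survey_dir")  # emits the CSV tables + ground_truth.json sidecar
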