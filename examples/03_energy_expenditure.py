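"""Energy expenditure: Schofield REE, count-based AEE, and the TEE link.

Shows the three energy quantities the pipeline moves between: resting
energy expenditure from anthropometry, activity energy expenditure from
counts per minute, and total energy expenditure with 10% of TEE attributed
to diet-induced thermogenesis.
"""
from wearval import Subject, aee_per_minute, convert_aee_tee, schofield_ree

s = Subject("demo", height_cm=175, weight_kg=75, age_y=30, sex="male")
ree = schofield_ree(s)
print(f"Schofield REE for a 30 y, 75 kg male: {ree:.1f} kcal/day")

for cpm in (0, 1000, 3000, 8000):
    kcal = aee_per_minute(cpm, s.weight_kg, "freedson_combo_1998")
    print(f"  {cpm:>5} counts/min -> {kcal:.3f} kcal/min")
# below ~1950 CPM the Williams work-energy equation applies; above it the
# count/body-mass regression takes over

aee = 600.0
tee = convert_aee_tee(aee, ree, "aee_to_tee")
print(f"daily AEE {aee:.0f} kcal + REE {ree:.0f} kcal -> TEE {tee:.1f} kcal "
      f"(DIT share {(tee - aee - ree) / tee:.0%})")
print(f"inverse: {convert_aee_tee(tee, ree, 'tee_to_aee'):.1f} kcal AEE")
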