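"""Simulate a study cohort and one subject's ground-truth day.

Draws 50 adults (heights/weights/ages truncated to realistic ranges), then
builds a minute-by-minute ground-truth profile for the first subject: a
single nonwear block followed by bout-structured activity.  The printed
totals are the quantities every device rendering is later judged against.
"""
import numpy as np

from wearval import ProfileConfig, simulate_profile, simulate_subjects

subjects = simulate_subjects(50, seed=1)
heights = np.array([s.height_cm for s in subjects])
print(f"cohort: n={len(subjects)}, mean height {heights.mean():.1f} cm, "
      f"{np.mean([s.sex == 'female' for s in subjects]):.0%} female")

profile = simulate_profile(subjects[0], ProfileConfig(), seed=7)
totals = profile.zone_totals()
print(f"\nsubject {subjects[0].id} ({subjects[0].sex}, {subjects[0].age_y:.0f} y, "
      f"{subjects[0].weight_kg:.0f} kg), one 24 h day:")
for zone, minutes in totals.items():
    print(f"  {zone:>14}: {minutes:4d} min")
print(f"  ground truth: {profile.total_steps} steps, "
      f"{profile.total_aee:.0f} kcal activity energy")
# zone minutes sum to 1440; steps and energy are zero while not worn
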