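"""From raw 10 s epochs to daily intensity-zone minutes.

Renders a triaxial accelerometer stream from ground truth, reintegrates it
to 60 s epochs, detects nonwear from zero-count runs (90 min rule), and
classifies each worn minute with the vector-magnitude cut points.  With an
unbiased, noise-free device the derived zone minutes equal the truth.
"""
from wearval import (
    ProfileConfig,
    builtin_cutpoints,
    detect_nonwear,
    hecht_params,
    reintegrate,
    simulate_profile,
    simulate_subjects,
    triaxial_accelerometer,
    zone_minutes,
)
from wearval.synthetic import render_counts

subject = simulate_subjects(1, seed=3)[0]
profile = simulate_profile(subject, ProfileConfig(), seed=3)
series = render_counts(profile, triaxial_accelerometer("hip"), seed=3)
print(f"rendered {series.n_epochs} epochs of {series.epoch_length} s")

minute = reintegrate(series, 60)
mask = detect_nonwear(minute, hecht_params())
print(f"wear time detected: {mask.wear_minutes} min "
      f"(truth: {int(profile.worn.sum())} min)")

oc = zone_minutes(minute, builtin_cutpoints()["sasaki_vm3"], mask)
print(f"sedentary {oc.sedentary_min:.0f} | light {oc.light_min:.0f} | "
      f"moderate {oc.moderate_min:.0f} | vigorous {oc.vigorous_min:.0f} "
      f"| MVPA {oc.mvpa_min:.0f} min; steps {oc.steps:.0f}; "
      f"valid day: {oc.valid}")
# a valid day needs >= 10 h of wear on every compared instrument
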