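# Methods

This note documents the models, parameter choices and numerical decisions
behind `wearval`, and what the synthetic study can and cannot show about
real device data.

## Study design emulated

One consumer watch (daily summaries only: zone minutes, steps, TEE) is
validated against six criterion combinations derived from four
research-grade instruments worn simultaneously for one 24 h day: a wrist
and a hip triaxial accelerometer, each analysed on the vertical axis
(uniaxial cut points, uniaxial energy model) and as vector magnitude
(VM cut points, VM energy model), and two chest-worn uniaxial
accelerometers. Analyses are pairwise-complete: a subject enters a
comparison only if both instruments record a valid day (≥ 10 h detected
wear). Steps are compared only against instruments that report steps
(the accelerometers; chest devices do not), and where one side lacks AEE
or TEE the energy conversion is applied to that side exactly once.

## Processing pipeline

**Reintegration.** Counts and steps are summed into non-overlapping 60 s
windows aligned to the series start. A trailing partial window is dropped,
never padded — padding would fabricate counts. Windows align to the series
start time, not wall-clock minutes.

**Nonwear.** A minute is nonwear iff it lies in at least one interval that
starts and ends on zero-activity minutes (vector magnitude for triaxial
input, the vertical axis otherwise), spans at least the rule's window, and
contains at most `spike_tolerance` non-zero minutes, each below
`spike_ceiling` CPM. Defaults: window 90 min for the intensity branch
(Hecht-style) and 60 min for the energy branch (Troiano-style), both with
2 spike minutes under 100 CPM; all parameters are configurable. The
declarative interval definition makes the implementation directly
checkable against a brute-force enumeration oracle, which the tests do on
series up to 2000 minutes. The rule runs on uniaxial chest data as well,
although it was designed for triaxial input; that known limitation is kept,
not fixed. A per-device `force_wear` override exists for wearers known to
have kept the device on.

**Intensity classification.** Cut-point intervals are closed on their
printed integer thresholds ("100–1951" means [100, 1951]). Classification
uses each zone's inclusive lower bound, so fractional CPM produced by a
calibration hook is assigned to the zone whose lower bound it last passed,
with no gaps or ties. A per-epoch calibration hook (default identity) is
the place for wrist-to-hip count conversions, for which no published
function exists. Very-vigorous minutes are folded into vigorous before any
comparison, and MVPA = moderate + vigorous. The chest cut-point set has no
very-vigorous zone; its vigorous zone is open-ended.

**Energy.** `aee_per_minute` applies the Williams work–energy equation
(0.0000191 kcal per CPM per kg) at or below the model's switch point and a
linear count/body-mass regression above it: the uniaxial combination
switches at 1951 CPM to 0.00094·CPM + 0.1346·kg − 7.37418, the VM
combination at 2453 VM-CPM to 0.001064·VM + 0.087512·kg − 5.500229. The
published combinations are not continuous at the switch point — for light
subjects the VM regression actually steps *down* — so monotonicity in CPM
holds within each branch but not across the switch; `switch_discontinuity`
reports the jump instead of smoothing it away. Schofield REE uses the
weight-based adult bands with the upper age edge inclusive (age 30 falls
in the 18–30 band). The AEE↔TEE conversion defines diet-induced
thermogenesis as a fixed fraction f = 0.10 *of TEE*, giving
TEE = (AEE + REE)/(1 − f); the inverse direction floors AEE at zero, and
away from the floor the two directions are exact inverses.

## Agreement battery

Pearson r uses paired nonparametric case resampling (default 1000
resamples) with a percentile 95% CI; degenerate (constant) resamples are
dropped. The bootstrap scheme is a package choice — case resampling with a
percentile interval is the standard default when none is specified.
ICC(2,1) comes from the two-way ANOVA mean squares,
ICC = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with the
F-distribution CI using Satterthwaite degrees of freedom; the tests verify
it against both a hand ANOVA decomposition and an independent library
implementation. Bland–Altman limits are mean ± 1.96 s with a t-based CI
for the mean difference and Var(LoA) ≈ 3s²/n for the limits. MAPE drops
(and logs) subjects with a zero criterion value rather than erroring,
since synthetic days can legitimately contain zero-valued outcomes.
Verbal labels: Evans bands for |r| (boundaries .2/.4/.6/.8 assigned to the
upper band, resolving the overlap in the conventional listing), and the
ICC label is the range of Koo–Li categories spanned by the ICC's 95% CI
(e.g. "poor to good"). The step-goal test treats exactly 10,000 steps as
meeting the target. Shapiro–Wilk is computed on the paired differences —
the quantity whose normality the Bland–Altman limits assume.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Cohort.** Height, weight and age are truncated normals with mean/SD
(173.7 ± 10.1 cm, 75.3 ± 16.4 kg, 45.1 ± 15.5 y) and ranges (152–193,
49–125, 19–74) typical of a convenience-sampled adult validation cohort;
48% female. The truncated distribution's location is re-solved so its
*truncated* mean equals the stated mean (plain truncation would shift it).

**Ground truth.** One day per subject: a single nonwear block (truncated
normal, 475 ± 60 min within 330–620 — sleep plus charging time) followed by
worn minutes whose zone totals are an exact multinomial draw from the
configured shares (base: sedentary .565, light .36, moderate .055,
vigorous .015, very vigorous .005). The totals are laid out as
geometric-length bouts, so minute sequences have realistic run structure
while totals remain exactly multinomial — which is what makes the
binomial-bound recovery tests valid. Between-subject heterogeneity scales
the active shares by a log-normal multiplier (σ = 0.5) plus a Dirichlet
draw, producing a realistic spread of daily steps (roughly 4k–30k, with a
substantial fraction below the 10,000-step target). Steps are Poisson per
worn minute with zone cadences 0/15/100/130/150 steps/min; the light-zone
cadence is deliberately far below a walking cadence because free-living
light-intensity minutes are mostly non-ambulatory — a walking-like cadence
there would push every subject far past 10,000 steps/day and degenerate the
specificity analysis. Ground-truth AEE applies the uniaxial combination
model to the (rounded) reference zone-centre CPM, so a bias-free rendered
device reproduces it exactly.

**Rendering.** Each worn minute's zone maps to a centre CPM — the midpoint
of the zone's closed interval, or 1.5× the lower bound for open-ended top
zones — times the device's (possibly per-zone) gain, plus truncated
Gaussian noise, rounded to integer counts and spread over the device's
native epochs (10 s triaxial, 15 s chest) with the remainder on the
earliest epochs so reintegration conserves totals. Triaxial devices carry
separate vertical-axis and vector-magnitude centres; the lateral axes are
set to √((VM² − a₁²)/2) so both the uniaxial and the VM analysis recover
the true zone when bias and noise are off. Nonwear minutes render as zero
counts, which is exactly what the zero-run detector consumes. Summary-only
devices report truth totals scaled by their gains with optional
heteroscedastic reporting noise (absolute + relative components), and TEE
as biased truth-AEE converted through the subject's Schofield REE. Chest
devices' daily energy comes from a truth-derived sidecar (their onboard
combined-sensing energy model is proprietary and out of scope).

**Default error model** (the `default_roster`): the watch underreports
sedentary/light minutes (gains 0.92/0.88), overreports moderate/vigorous
(1.6/1.4) and steps (+15%) and energy (+10%), with day-level reporting
noise; accelerometers carry 350 CPM epoch noise (wrist gain 1.2 — wrist
placements see more movement), chest devices 25 CPM with small energy
biases. These values are chosen once to produce group means and
disagreement patterns of the size consumer-device validation studies
report; they are illustrative, not estimates of any particular product.

**Recovery roster.** Exact end-to-end recovery (every MAPE 0, every r 1)
is only possible when all instruments share one energy definition: the
uniaxial and VM combination models give different kcal for the same ground
truth by construction — the same heterogeneity real studies face when
comparing devices that embed different equations. The `recovery_roster`
therefore uses the uniaxial model on the vertical axis for every epoch
analysis and truth-derived energy for chest devices, with all gains 1 and
all noise 0.

## What passing tests do and do not show

The synthetic data exercise the pipeline's logic — classification,
nonwear, energy arithmetic, pairing, statistics — under known truth. They
do not emulate: raw sub-second accelerations, posture or sleep, autocorrelated
count noise within a zone, device clock drift, or the proprietary
classification/energy algorithms inside real products. Agreement
statistics computed on synthetic data therefore validate the *method*, not
any real device; their magnitudes depend on the injected error model.

## Problem sizes and numerics

The shipped study size is 50 subjects × 1 day × 5 devices (8640 or 5760
native epochs per device-day), with 1000 bootstrap resamples — a full run
takes a few seconds on one CPU, and the whole test suite under half a
minute. All randomness flows from one master seed through
`numpy.random.default_rng`; identical config + seed give byte-identical
report CSVs. Epoch files store ISO-8601 local timestamps (single-day
recordings, no time zones); a one-row epoch file cannot carry its epoch
length (inferred from timestamp spacing) and defaults to 60 s.

## Known limitations

* The CSV dialects are faithful-in-spirit emulations (header shapes,
  preamble length), not byte-level clones of any vendor export.
* The ICC CI uses the standard F/Satterthwaite approximation; for n < 10
  it can be wide and occasionally negative at the lower end.
* The nonwear rule pair (90/60 min) is configurable but the defaults are
  frozen; no sleep detection is attempted, so long still periods with the
  device on are indistinguishable from nonwear — as in real actigraphy.
* Bout-based MVPA, child/adolescent cut points and heart-rate-based energy
  models are out of scope.
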