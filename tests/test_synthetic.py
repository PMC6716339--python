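"""Synthetic cohort, ground-truth profiles and device rendering."""
import numpy as np
import pytest

from wearval.containers import NONWEAR
from wearval.energy import convert_aee_tee, schofield_ree
from wearval.intensity import builtin_cutpoints, classify_epoch
from wearval.preprocess import reintegrate, vector_magnitude
from wearval.synthetic import (
    COHORT_DEFAULTS,
    DeviceModel,
    ProfileConfig,
    chest_accelerometer,
    consumer_watch,
    render_counts,
    render_summary,
    simulate_profile,
    simulate_subjects,
    triaxial_accelerometer,
    zone_centers,
)

UNI = builtin_cutpoints()["freedson_matthews_uniaxial"]
VM = builtin_cutpoints()["sasaki_vm3"]


class TestSimulateSubjects:
    def test_seed_reproducibility(self):
        assert simulate_subjects(50, seed=1) == simulate_subjects(50, seed=1)
        assert simulate_subjects(50, seed=1) != simulate_subjects(50, seed=2)

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            simulate_subjects(0, seed=1)

    def test_attributes_match_population_mean_and_range(self):
        subjects = simulate_subjects(1000, seed=7)
        heights = np.array([s.height_cm for s in subjects])
        mean, sd, lo, hi = COHORT_DEFAULTS["height_cm"]
        assert abs(heights.mean() - mean) < sd / np.sqrt(1000)  # within 1 SE
        assert heights.min() >= lo and heights.max() <= hi
        ages = np.array([s.age_y for s in subjects])
        assert ages.min() >= 19 and ages.max() <= 74
        frac_female = np.mean([s.sex == "female" for s in subjects])
        assert 0.40 < frac_female < 0.56


class TestSimulateProfile:
    def test_zero_probability_zone_never_appears(self, subject):
        cfg = ProfileConfig(zone_probs={
            "sedentary": 0.6, "light": 0.3, "moderate": 0.1,
            "vigorous": 0.0, "very_vigorous": 0.0})
        prof = simulate_profile(subject, cfg, seed=3)
        assert prof.zone_totals()["vigorous"] == 0
        assert prof.zone_totals()["very_vigorous"] == 0

    def test_full_wear_configuration_has_no_nonwear(self, subject):
        cfg = ProfileConfig(nonwear_mean=0, nonwear_sd=0, nonwear_range=(0, 0))
        prof = simulate_profile(subject, cfg, seed=3)
        assert prof.zone_totals()[NONWEAR] == 0

    def test_infeasible_minimum_wear_rejected(self):
        with pytest.raises(ValueError):
            ProfileConfig(min_wear_minutes=1441)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ProfileConfig(zone_probs={"sedentary": 0.5, "light": 0.4})

    def test_zone_totals_are_multinomial(self, subject):
        """Across replicates the moderate fraction sits within the binomial
        3-sigma band of its configured probability."""
        p_mod = 0.1
        cfg = ProfileConfig(zone_probs={
            "sedentary": 0.6, "light": 0.25, "moderate": p_mod,
            "vigorous": 0.04, "very_vigorous": 0.01})
        worn = mod = 0
        seed = 0
        while worn < 10_000:
            prof = simulate_profile(subject, cfg, seed=seed)
            totals = prof.zone_totals()
            worn += 1440 - totals[NONWEAR]
            mod += totals["moderate"]
            seed += 1
        se = np.sqrt(p_mod * (1 - p_mod) / worn)
        assert abs(mod / worn - p_mod) < 3 * se

    def test_structure_invariants(self, profile):
        totals = profile.zone_totals()
        assert sum(totals.values()) == 1440
        assert np.all(profile.minute_steps[~profile.worn] == 0)
        assert profile.worn.sum() >= 600
        assert np.all(profile.minute_aee >= 0)


class TestRenderCounts:
    def test_bias_free_rendering_recovers_every_worn_zone(self, profile):
        dev = triaxial_accelerometer("ag")
        series = render_counts(profile, dev, seed=1)
        minute = reintegrate(series, 60)
        uni_zones = classify_epoch(minute.axis1, UNI)
        vm_zones = classify_epoch(vector_magnitude(minute), VM)
        worn = profile.worn
        assert np.all(uni_zones[worn] == profile.minute_zone[worn])
        assert np.all(vm_zones[worn] == profile.minute_zone[worn])

    def test_nonwear_minutes_render_as_zero_epochs(self, profile):
        series = render_counts(profile, triaxial_accelerometer("ag"), seed=1)
        k = 60 // series.epoch_length
        nw = np.repeat(~profile.worn, k)
        assert np.all(series.axis1[nw] == 0)
        assert np.all(series.axis2[nw] == 0)
        assert np.all(series.steps[nw] == 0)

    def test_rendering_is_seed_deterministic(self, profile):
        dev = triaxial_accelerometer("ag", cpm_noise_sd=200.0)
        assert render_counts(profile, dev, seed=5) == render_counts(profile, dev, seed=5)
        assert render_counts(profile, dev, seed=5) != render_counts(profile, dev, seed=6)

    def test_noise_misclassification_only_at_boundary_crossings(self, profile):
        """With count noise on, a worn minute misclassifies iff its rendered
        CPM left the truth zone's printed interval (brute-force check)."""
        dev = chest_accelerometer("ah", cpm_noise_sd=40.0)
        series = render_counts(profile, dev, seed=9)
        minute = reintegrate(series, 60)
        cuts = builtin_cutpoints()["schrack_actiheart"]
        intervals = cuts.intervals()
        got = classify_epoch(minute.axis1, cuts)
        for m in np.flatnonzero(profile.worn):
            cpm = minute.axis1[m]
            truth = profile.minute_zone[m]
            truth_chest = "vigorous" if truth == "very_vigorous" else truth
            lo, hi = intervals[truth_chest]
            inside = cpm >= lo and (hi is None or cpm <= hi)
            assert (got[m] == truth_chest) == inside

    def test_summary_device_rejected(self, profile):
        with pytest.raises(ValueError):
            render_counts(profile, consumer_watch(), seed=1)

    def test_steps_conserved_through_native_epochs(self, profile):
        series = render_counts(profile, triaxial_accelerometer("ag"), seed=1)
        assert series.steps.sum() == profile.total_steps


class TestRenderSummary:
    def test_unit_gain_equals_truth_totals(self, profile, subject):
        oc = render_summary(profile, subject, consumer_watch(), seed=1)
        totals = profile.zone_totals()
        assert oc.steps == profile.total_steps
        assert oc.sedentary_min == totals["sedentary"]
        assert oc.vigorous_min == totals["vigorous"] + totals["very_vigorous"]
        assert oc.wear_min == profile.worn.sum()

    def test_step_gain_applies_with_rounding(self, profile, subject):
        dev = consumer_watch(step_gain=1.2)
        oc = render_summary(profile, subject, dev, seed=1)
        assert oc.steps == round(1.2 * profile.total_steps)

    def test_tee_composes_truth_aee_with_schofield_ree(self, profile, subject):
        oc = render_summary(profile, subject, consumer_watch(), seed=1)
        expect = convert_aee_tee(profile.total_aee, schofield_ree(subject), "aee_to_tee")
        assert oc.tee_kcal == pytest.approx(expect, rel=1e-12)

    def test_epoch_device_rejected(self, profile, subject):
        with pytest.raises(ValueError):
            render_summary(profile, subject, triaxial_accelerometer("ag"), seed=1)


class TestDeviceModel:
    def test_zone_centers_lie_inside_their_zone(self):
        for name, cuts in builtin_cutpoints().items():
            for zone, center in zone_centers(cuts).items():
                assert classify_epoch(center, cuts) == zone

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            DeviceModel("x", axes=2, native_epoch=10)
        with pytest.raises(ValueError):
            DeviceModel("x", axes=1, native_epoch=7)
        with pytest.raises(ValueError):
            DeviceModel("x", axes=1, native_epoch=10, step_gain=0.0)
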