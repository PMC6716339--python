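"""Synthetic free-living study generator.

No raw recordings from the validation study were ever deposited, so this
module generates the whole study from scratch: a cohort of adults, a
ground-truth minute-by-minute activity profile per subject, and per-device
renderings of that truth — epoch-level count streams for research
accelerometers and daily summaries for a consumer watch — with *known*
injected measurement error.  Because the injected bias and noise are known,
every downstream stage (classification, nonwear detection, energy
equations, agreement statistics) can be tested by parameter recovery.

Design of the day model
-----------------------
One 24 h day per subject (as in the study).  The day opens with a single
nonwear block (sleep plus charging/shower time); the remaining worn minutes
are assigned intensity zones by an exact multinomial draw over the
configured zone probabilities and then laid out as bouts (runs of the same
zone with geometric lengths), so zone *totals* are exactly multinomial
while the minute sequence has realistic bout structure.  Steps are Poisson
per worn minute with zone-dependent cadences; ground-truth activity energy
expenditure applies the uniaxial combination model to the reference
zone-centre CPM, so a bias-free rendered device reproduces it exactly.

Rendering inverts cut-point classification: each worn minute's zone maps to
a device- and zone-specific centre CPM, is scaled by the device's
multiplicative bias, perturbed with truncated Gaussian noise, rounded to
integer counts and spread over the device's native epochs.  Nonwear minutes
render as zero counts.  Triaxial devices receive a vertical-axis centre and
a vector-magnitude centre per zone so that both the uniaxial and the
vector-magnitude analysis recover the true zone when bias and noise are off.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MINUTES_PER_DAY, NONWEAR, ZONES, CountSeries, DailyOutcome, Subject
from .energy import aee_per_minute, convert_aee_tee, schofield_ree
from .intensity import CutPointSet, builtin_cutpoints

# --- cohort ---------------------------------------------------------------

#: Cohort attribute distributions: mean, SD and truncation range for a
#: population like the study's (N=50 adults, convenience-sampled for range).
COHORT_DEFAULTS = {
    "height_cm": (173.7, 10.1, 152.0, 193.0),
    "weight_kg": (75.3, 16.4, 49.0, 125.0),
    "age_y": (45.1, 15.5, 19.0, 74.0),
}
FEMALE_FRACTION = 0.48


def _mean_matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal on [lo, hi] whose *truncated* mean equals ``mean``.

    Plain truncation shifts the mean whenever the range is asymmetric; the
    location is re-solved so the generated attribute means match the
    population means the defaults encode.
    """

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = optimize.brentq(trunc_mean, mean - 2 * sd, mean + 2 * sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def simulate_subjects(n: int, seed: int) -> list:
    """Draw ``n`` synthetic adults; reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (mean, sd, lo, hi) in COHORT_DEFAULTS.items():
        dist = _mean_matched_truncnorm(mean, sd, lo, hi)
        cols[name] = dist.rvs(size=n, random_state=rng)
    sexes = np.where(rng.random(n) < FEMALE_FRACTION, "female", "male")
    return [
        Subject(
            id=f"S{i + 1:03d}",
            height_cm=round(float(cols["height_cm"][i]), 1),
            weight_kg=round(float(cols["weight_kg"][i]), 1),
            age_y=float(int(round(cols["age_y"][i]))),
            sex=str(sexes[i]),
        )
        for i in range(n)
    ]


# --- ground-truth profiles -------------------------------------------------

#: Steps per worn minute by zone (Poisson rates).  Sedentary minutes are
#: non-ambulatory; light-intensity minutes are mostly puttering, so their
#: average cadence is far below a walking cadence.
STEP_RATES = {
    "sedentary": 0.0, "light": 15.0, "moderate": 100.0,
    "vigorous": 130.0, "very_vigorous": 150.0,
}


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of the synthetic day.

    ``zone_probs`` are the expected zone shares over worn minutes (must sum
    to 1); zone totals are drawn exactly multinomially from them.  The
    nonwear block length is a truncated-normal draw.  ``mean_bout_min``
    controls the geometric bout lengths used to lay the minutes out.
    """

    zone_probs: Dict[str, float] = field(default_factory=lambda: {
        "sedentary": 0.565, "light": 0.36, "moderate": 0.055,
        "vigorous": 0.015, "very_vigorous": 0.005,
    })
    nonwear_mean: float = 475.0
    nonwear_sd: float = 60.0
    nonwear_range: tuple = (330.0, 620.0)
    min_wear_minutes: int = 600
    mean_bout_min: Dict[str, float] = field(default_factory=lambda: {
        "sedentary": 20.0, "light": 8.0, "moderate": 6.0,
        "vigorous": 4.0, "very_vigorous": 2.0,
    })
    step_rates: Dict[str, float] = field(default_factory=lambda: dict(STEP_RATES))
    #: CPM rendered/assumed for each zone when computing ground-truth AEE;
    #: defaults to the uniaxial reference centres.
    reference_centers: Optional[Dict[str, float]] = None
    ee_method: str = "freedson_combo_1998"

    def __post_init__(self) -> None:
        total = sum(self.zone_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"zone probabilities must sum to 1 (got {total})")
        if self.min_wear_minutes > MINUTES_PER_DAY:
            raise ValueError("min_wear_minutes cannot exceed 1440")


def zone_centers(cuts: CutPointSet, top_factor: float = 1.5) -> Dict[str, float]:
    """Default rendering centre CPM per zone: the midpoint of each closed
    interval; the open-ended top zone uses its lower bound × ``top_factor``.

    Midpoints keep rendering invertible by classification: a bias-free,
    noise-free rendering classifies back to the zone it came from with
    maximal margin.
    """
    centers = {}
    for zone, (lo, hi) in cuts.intervals().items():
        centers[zone] = lo * top_factor if hi is None else (lo + hi) / 2.0
    return centers


@dataclass
class TruthProfile:
    """Ground-truth minute trajectory for one subject-day."""

    subject_id: str
    minute_zone: np.ndarray  # str per minute, NONWEAR or a zone name
    minute_steps: np.ndarray  # int per minute, 0 during nonwear
    minute_aee: np.ndarray  # kcal per minute, 0 during nonwear
    weight_kg: float

    def __post_init__(self) -> None:
        if len(self.minute_zone) != MINUTES_PER_DAY:
            raise ValueError("profile must cover exactly 1440 minutes")
        nw = self.minute_zone == NONWEAR
        if np.any(self.minute_steps[nw] != 0):
            raise ValueError("steps must be zero during nonwear")

    @property
    def worn(self) -> np.ndarray:
        return self.minute_zone != NONWEAR

    def zone_totals(self) -> Dict[str, int]:
        out = {z: int(np.sum(self.minute_zone == z)) for z in ZONES}
        out[NONWEAR] = int(np.sum(~self.worn))
        return out

    @property
    def total_steps(self) -> int:
        return int(self.minute_steps.sum())

    @property
    def total_aee(self) -> float:
        return float(self.minute_aee.sum())


def simulate_profile(subject: Subject, config: ProfileConfig, seed: int) -> TruthProfile:
    """Simulate one subject-day of ground truth.

    Zone totals over worn minutes are an exact multinomial draw from
    ``config.zone_probs``; the nonwear block sits at the start of the day.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.nonwear_range
    nonwear_len = int(np.clip(rng.normal(config.nonwear_mean, config.nonwear_sd), lo, hi))
    nonwear_len = min(nonwear_len, MINUTES_PER_DAY - config.min_wear_minutes)
    worn_len = MINUTES_PER_DAY - nonwear_len

    zones = [z for z in ZONES if config.zone_probs.get(z, 0.0) > 0]
    probs = np.array([config.zone_probs[z] for z in zones])
    counts = rng.multinomial(worn_len, probs / probs.sum())

    # Lay out the exact totals as bouts: pick a zone in proportion to its
    # remaining minutes, then emit a geometric-length run of it.
    remaining = dict(zip(zones, counts))
    sequence = []
    while sum(remaining.values()) > 0:
        avail = [z for z in zones if remaining[z] > 0]
        w = np.array([remaining[z] for z in avail], dtype=float)
        z = avail[rng.choice(len(avail), p=w / w.sum())]
        mean_bout = config.mean_bout_min.get(z, 5.0)
        bout = min(int(rng.geometric(1.0 / max(mean_bout, 1.0))), remaining[z])
        sequence.extend([z] * bout)
        remaining[z] -= bout

    minute_zone = np.array([NONWEAR] * nonwear_len + sequence, dtype=object)
    assert len(minute_zone) == MINUTES_PER_DAY

    rates = np.array([0.0 if z == NONWEAR else config.step_rates.get(z, 0.0)
                      for z in minute_zone])
    minute_steps = rng.poisson(rates)

    centers = config.reference_centers or zone_centers(
        builtin_cutpoints()["freedson_matthews_uniaxial"]
    )
    minute_aee = np.zeros(MINUTES_PER_DAY)
    for z in zones:
        sel = minute_zone == z
        cpm = float(np.rint(centers[z]))
        minute_aee[sel] = aee_per_minute(cpm, subject.weight_kg, config.ee_method)

    return TruthProfile(
        subject_id=subject.id,
        minute_zone=minute_zone,
        minute_steps=minute_steps.astype(int),
        minute_aee=minute_aee,
        weight_kg=subject.weight_kg,
    )


# --- device models and rendering ------------------------------------------

GainLike = Union[float, Dict[str, float]]


@dataclass(frozen=True)
class DeviceModel:
    """A wearable's measurement-error model.

    ``cpm_gain`` (scalar or per-zone) multiplies the rendered centre CPM —
    for summary-only devices it instead multiplies the reported zone
    minutes.  ``cpm_noise_sd`` adds truncated Gaussian noise to each worn
    minute's CPM.  ``zone_center_cpm`` maps each zone to the CPM rendered
    for it under the device's reference cut-point set; triaxial devices
    additionally carry ``zone_center_axis1`` (vertical-axis centres) so
    uniaxial re-analysis of the same stream also recovers the truth.
    Summary-only devices (consumer watches) report daily totals directly,
    with optional additive reporting noise.
    """

    name: str
    axes: int  # 1 or 3
    native_epoch: int  # seconds, must divide 60
    cpm_gain: GainLike = 1.0
    cpm_noise_sd: float = 0.0
    step_gain: float = 1.0
    summary_only: bool = False
    zone_center_cpm: Optional[Dict[str, float]] = None
    zone_center_axis1: Optional[Dict[str, float]] = None
    ee_gain: float = 1.0
    ee_noise_sd: float = 0.0  # kcal, daily EE reporting noise
    summary_minutes_noise_sd: float = 0.0  # min, absolute per-zone reporting noise
    #: relative part of the per-zone reporting noise: sd grows with the true
    #: minutes, so small zones (vigorous) are not drowned by a fixed floor
    summary_minutes_noise_frac: float = 0.0
    summary_steps_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.axes not in (1, 3):
            raise ValueError("axes must be 1 or 3")
        if 60 % self.native_epoch != 0:
            raise ValueError("native_epoch must divide 60")
        gains = (self.cpm_gain.values() if isinstance(self.cpm_gain, dict)
                 else [self.cpm_gain])
        if any(g <= 0 for g in gains) or self.step_gain <= 0 or self.ee_gain <= 0:
            raise ValueError("gains must be positive")

    def gain_for(self, zone: str) -> float:
        if isinstance(self.cpm_gain, dict):
            return self.cpm_gain.get(zone, 1.0)
        return self.cpm_gain


def _default_centers(axes: int):
    sets = builtin_cutpoints()
    if axes == 3:
        return zone_centers(sets["sasaki_vm3"]), zone_centers(
            sets["freedson_matthews_uniaxial"]
        )
    return zone_centers(sets["freedson_matthews_uniaxial"]), None


def triaxial_accelerometer(name: str, **kwargs) -> DeviceModel:
    """Research-style triaxial accelerometer exporting 10 s epochs."""
    vm, ax1 = _default_centers(3)
    kwargs.setdefault("zone_center_cpm", vm)
    kwargs.setdefault("zone_center_axis1", ax1)
    return DeviceModel(name=name, axes=3, native_epoch=10, **kwargs)


def chest_accelerometer(name: str, **kwargs) -> DeviceModel:
    """Chest-worn uniaxial accelerometer exporting 15 s epochs.

    Centres follow the chest cut-point set; a very-vigorous minute renders
    above the (open-ended) vigorous threshold, as the chest set folds the
    top zones together.
    """
    centers = zone_centers(builtin_cutpoints()["schrack_actiheart"])
    centers = dict(centers, very_vigorous=centers["vigorous"] * 4.0 / 3.0)
    kwargs.setdefault("zone_center_cpm", centers)
    return DeviceModel(name=name, axes=1, native_epoch=15, **kwargs)


def consumer_watch(name: str = "watch", **kwargs) -> DeviceModel:
    """Summary-only consumer watch: daily zone minutes, steps and TEE."""
    kwargs.setdefault("summary_only", True)
    return DeviceModel(name=name, axes=3, native_epoch=60, **kwargs)


def _spread_integer(total: int, k: int) -> np.ndarray:
    """Split an integer count over k epochs, remainder to the earliest."""
    base, rem = divmod(int(total), k)
    out = np.full(k, base, dtype=float)
    out[:rem] += 1
    return out


def render_counts(profile: TruthProfile, device: DeviceModel, seed: int,
                  start_time="2018-05-01 00:00:00") -> CountSeries:
    """Render a ground-truth profile as the device's native epoch stream.

    With unit gain and zero noise the rendered minute CPM is the rounded
    zone centre, so classification with the device's reference cut points
    recovers the true zone of every worn minute.
    """
    if device.summary_only:
        raise ValueError(f"device {device.name} is summary-only; use render_summary")
    rng = np.random.default_rng(seed)
    k = 60 // device.native_epoch
    n = MINUTES_PER_DAY * k
    axis1 = np.zeros(n)
    axis2 = np.zeros(n) if device.axes == 3 else None
    axis3 = np.zeros(n) if device.axes == 3 else None
    steps = np.zeros(n)

    centers = device.zone_center_cpm
    if centers is None:
        centers, ax1_centers = _default_centers(device.axes)
    else:
        ax1_centers = device.zone_center_axis1

    for m in range(MINUTES_PER_DAY):
        zone = profile.minute_zone[m]
        if zone == NONWEAR:
            continue
        gain = device.gain_for(zone)
        sl = slice(m * k, (m + 1) * k)
        noise = (rng.normal(0.0, device.cpm_noise_sd)
                 if device.cpm_noise_sd > 0 else 0.0)
        ref = max(0.0, centers[zone] * gain + noise)
        if device.axes == 1:
            axis1[sl] = _spread_integer(int(np.rint(ref)), k)
        else:
            noise_u = (rng.normal(0.0, device.cpm_noise_sd)
                       if device.cpm_noise_sd > 0 else 0.0)
            u = max(0.0, ax1_centers[zone] * gain + noise_u)
            v = max(ref, u)  # vector magnitude can never undershoot an axis
            a1 = int(np.rint(u))
            a23 = int(np.rint(math.sqrt(max(v * v - u * u, 0.0) / 2.0)))
            axis1[sl] = _spread_integer(a1, k)
            axis2[sl] = _spread_integer(a23, k)
            axis3[sl] = _spread_integer(a23, k)
        n_steps = int(np.rint(device.step_gain * profile.minute_steps[m]))
        steps[sl] = _spread_integer(n_steps, k)

    return CountSeries(
        subject_id=profile.subject_id,
        device=device.name,
        start_time=pd.Timestamp(start_time),
        epoch_length=device.native_epoch,
        axis1=axis1,
        axis2=axis2,
        axis3=axis3,
        steps=steps,
    )


def render_summary(profile: TruthProfile, subject: Subject, device: DeviceModel,
                   seed: int, date: str = "2018-05-01",
                   dit_fraction: float = 0.10) -> DailyOutcome:
    """Render a summary-only device's daily report from ground truth.

    Zone minutes, steps and activity energy are the truth totals scaled by
    the device's gains (very-vigorous folded into vigorous, as the watch
    reports a single "high" zone) plus optional reporting noise; TEE is the
    biased AEE converted with the subject's Schofield REE.  With unit gains
    and zero noise the report equals the truth totals exactly.
    """
    if not device.summary_only:
        raise ValueError(f"device {device.name} is epoch-level; use render_counts")
    rng = np.random.default_rng(seed)
    totals = profile.zone_totals()
    mins = {}
    for zone in ("sedentary", "light", "moderate", "vigorous"):
        true_min = float(totals[zone])
        if zone == "vigorous":
            true_min += float(totals["very_vigorous"])
        val = true_min * device.gain_for(zone)
        sd = math.hypot(device.summary_minutes_noise_sd,
                        device.summary_minutes_noise_frac * true_min)
        if sd > 0:
            val += rng.normal(0.0, sd)
        mins[zone] = float(np.rint(max(0.0, val)))
    steps = device.step_gain * profile.total_steps
    if device.summary_steps_noise_sd > 0:
        steps += rng.normal(0.0, device.summary_steps_noise_sd)
    steps = float(np.rint(max(0.0, steps)))
    aee = device.ee_gain * profile.total_aee
    if device.ee_noise_sd > 0:
        aee += rng.normal(0.0, device.ee_noise_sd)
    aee = max(0.0, aee)
    tee = convert_aee_tee(aee, schofield_ree(subject), "aee_to_tee", dit_fraction)
    worn = float(np.sum(profile.worn))
    return DailyOutcome(
        subject_id=profile.subject_id,
        device=device.name,
        date=date,
        sedentary_min=mins["sedentary"],
        light_min=mins["light"],
        moderate_min=mins["moderate"],
        vigorous_min=mins["vigorous"],
        wear_min=worn,
        valid=worn >= 600,
        steps=steps,
        tee_kcal=tee,
    )


def perturb_zone_probs(base: Dict[str, float], rng: np.random.Generator,
                       activity_sigma: float = 0.5,
                       concentration: float = 60.0) -> Dict[str, float]:
    """Per-subject heterogeneity for the study generator.

    A log-normal activity multiplier scales the non-sedentary shares (some
    people move a lot more than others), sedentary absorbs the difference;
    a Dirichlet draw around the scaled shares adds day-to-day idiosyncrasy.
    """
    zones = list(base)
    p = np.array([base[z] for z in zones], dtype=float)
    active = np.array([z != "sedentary" for z in zones])
    m = rng.lognormal(0.0, activity_sigma)
    p[active] *= m
    active_total = min(p[active].sum(), 0.85)
    p[active] *= active_total / p[active].sum()
    p[~active] = 1.0 - active_total
    drawn = rng.dirichlet(np.maximum(concentration * p, 1e-3))
    return dict(zip(zones, drawn))
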