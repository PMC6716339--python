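"""End-to-end study orchestration.

``run_validation`` executes the whole design: simulate (or load) subjects,
render every device in the roster, derive per-device daily outcomes under
each device's analysis combinations (cut-point set × axis metric), and
compare the test device against every criterion combination with the full
agreement battery.  The default roster mirrors a one-day multi-device
validation study: one summary-only consumer watch on the wrist (the test
device) against six criterion combinations — a wrist and a hip triaxial
accelerometer each analysed on the vertical axis and as vector magnitude,
and two chest-worn uniaxial accelerometers.

Outcome availability follows what each instrument reports: steps are only
compared against devices that export steps; where one side lacks AEE or
TEE, the AEE↔TEE conversion (Schofield REE, 10% diet-induced
thermogenesis) is applied exactly once to that side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import agreement, epoch_io
from .containers import DailyOutcome, Subject, outcomes_to_frame
from .energy import EnergyParams, convert_aee_tee, daily_aee, schofield_ree
from .intensity import builtin_cutpoints, zone_minutes
from .preprocess import WearMask, detect_nonwear, hecht_params, reintegrate, troiano_params
from .synthetic import (
    DeviceModel,
    ProfileConfig,
    TruthProfile,
    chest_accelerometer,
    consumer_watch,
    perturb_zone_probs,
    render_counts,
    render_summary,
    simulate_profile,
    simulate_subjects,
    triaxial_accelerometer,
)

log = logging.getLogger(__name__)

ZONE_OUTCOMES = ("sedentary_min", "light_min", "moderate_min", "vigorous_min", "mvpa_min")
ALL_OUTCOMES = ZONE_OUTCOMES + ("steps", "aee_kcal", "tee_kcal")


@dataclass(frozen=True)
class Analysis:
    """One way of analysing an epoch device: a cut-point set + EE method."""

    cutpoints: str  # key into builtin_cutpoints()
    ee_method: Optional[str] = None  # None -> no EE from counts
    label: str = ""

    def name(self, device: str) -> str:
        return f"{device}:{self.label or self.cutpoints}"


@dataclass
class RosterEntry:
    """A device in the study, its role and how it is analysed."""

    device: DeviceModel
    role: str  # "test" | "criterion"
    placement: str = ""
    analyses: List[Analysis] = field(default_factory=list)
    reports_steps: bool = True
    #: chest devices carry truth-derived daily EE (their onboard EE model
    #: is proprietary); epoch EE from counts is then skipped.
    ee_from_truth: bool = False
    #: override for devices the wearer verifiably kept on: treat every
    #: minute as worn regardless of the zero-run detector.
    force_wear: bool = False


def default_roster(noise: bool = True) -> List[RosterEntry]:
    """The default study roster: consumer watch vs six criterion combinations.

    Device-error defaults encode the kind of behaviour consumer validation
    studies report — the watch overcounts steps and MVPA and carries
    day-level reporting noise; research devices are nearly unbiased with
    epoch-level count noise.
    """
    f = 1.0 if noise else 0.0
    watch = consumer_watch(
        "watch",
        cpm_gain={"sedentary": 0.92, "light": 0.88, "moderate": 1.6, "vigorous": 1.4},
        step_gain=1.15,
        ee_gain=1.10,
        summary_minutes_noise_sd=12.0 * f,
        summary_minutes_noise_frac=0.18 * f,
        summary_steps_noise_sd=1500.0 * f,
        ee_noise_sd=140.0 * f,
    )
    ag_kw = dict(cpm_noise_sd=350.0 * f)
    both_axes = [
        Analysis("freedson_matthews_uniaxial", "freedson_combo_1998", "cpm"),
        Analysis("sasaki_vm3", "freedson_vm3_combo_2011", "vm"),
    ]
    chest = [Analysis("schrack_actiheart", None, "cpm")]
    return [
        RosterEntry(watch, "test", placement="wrist"),
        # wrist-worn accelerometers see more movement than hip-worn ones
        RosterEntry(triaxial_accelerometer("ag_wrist", step_gain=1.04,
                                           cpm_gain=1.2 if noise else 1.0, **ag_kw),
                    "criterion", "wrist", list(both_axes)),
        RosterEntry(triaxial_accelerometer("ag_hip", **ag_kw),
                    "criterion", "hip", list(both_axes)),
        RosterEntry(chest_accelerometer("ah_upper", cpm_noise_sd=25.0 * f,
                                        cpm_gain=0.95 if noise else 1.0,
                                        ee_gain=1.0 if not noise else 0.97,
                                        ee_noise_sd=120.0 * f),
                    "criterion", "chest_upper", list(chest),
                    reports_steps=False, ee_from_truth=True),
        RosterEntry(chest_accelerometer("ah_lower", cpm_noise_sd=25.0 * f,
                                        ee_gain=1.0 if not noise else 0.98,
                                        ee_noise_sd=120.0 * f),
                    "criterion", "chest_lower", list(chest),
                    reports_steps=False, ee_from_truth=True),
    ]


def recovery_roster(consumer_step_gain: float = 1.0) -> List[RosterEntry]:
    """Bias-free, noise-free roster for parameter-recovery checks.

    Every epoch analysis uses the uniaxial combination EE model on the
    vertical axis so that all instruments share one energy definition;
    heterogeneous EE equations (as between real products) would differ
    even on identical ground truth.  ``consumer_step_gain`` optionally
    re-injects a known step bias into the watch so its downstream recovery
    can be checked.
    """
    roster = default_roster(noise=False)
    out = []
    for entry in roster:
        step_gain = consumer_step_gain if entry.role == "test" else 1.0
        device = replace(entry.device, cpm_gain=1.0, step_gain=step_gain, ee_gain=1.0)
        analyses = [replace(a, ee_method="freedson_combo_1998" if a.ee_method else None)
                    for a in entry.analyses]
        out.append(replace(entry, device=device, analyses=analyses))
    return out


@dataclass
class StudyConfig:
    """Everything needed to run (and exactly reproduce) one validation study."""

    n_subjects: int = 50
    seed: int = 0
    subjects_csv: Optional[str] = None
    roster: List[RosterEntry] = field(default_factory=default_roster)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    heterogeneity_sigma: float = 0.5
    bootstrap: int = 1000
    step_goal: float = 10000.0
    min_wear_hours: float = 10.0
    dit_fraction: float = 0.10
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        tests = [e for e in self.roster if e.role == "test"]
        crits = [e for e in self.roster if e.role == "criterion"]
        if len(tests) != 1:
            raise ValueError(f"roster must contain exactly one test device, found {len(tests)}")
        if not crits:
            raise ValueError("roster must contain at least one criterion device")

    @property
    def test_entry(self) -> RosterEntry:
        return next(e for e in self.roster if e.role == "test")

    @property
    def criterion_entries(self) -> List[RosterEntry]:
        return [e for e in self.roster if e.role == "criterion"]


@dataclass
class ValidationReport:
    """Bundle of tables produced by one run."""

    subjects: pd.DataFrame
    daily_outcomes: pd.DataFrame
    agreement: pd.DataFrame
    ba_data: pd.DataFrame  # per-subject scatter / Bland-Altman points
    sens_spec: pd.DataFrame
    log_lines: List[str]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.6g")
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.daily_outcomes.to_csv(out / "daily_outcomes.csv", index=False)
        self.agreement.to_csv(out / "agreement.csv", **kw)
        self.ba_data.to_csv(out / "ba_data.csv", **kw)
        self.sens_spec.to_csv(out / "sens_spec.csv", **kw)
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")


# --- derivation ------------------------------------------------------------

def derive_epoch_outcomes(series, subject: Subject, entry: RosterEntry,
                          truth: Optional[TruthProfile] = None,
                          min_wear_hours: float = 10.0,
                          dit_fraction: float = 0.10,
                          ee_sidecar: Optional[Dict[str, float]] = None,
                          rng: Optional[np.random.Generator] = None,
                          ) -> Dict[str, DailyOutcome]:
    """Daily outcomes for one epoch device, one per analysis combination.

    The intensity branch uses the Hecht-style nonwear rule; the energy
    branch recomputes nonwear with the Troiano-style rule, mirroring how
    the two branches are produced by different software in practice.
    ``ee_sidecar`` supplies a device-reported daily AEE (chest devices);
    otherwise EE comes from counts via the analysis' combination model.
    """
    minute = reintegrate(series, 60)
    if entry.force_wear:
        wear_intensity = wear_ee = WearMask(
            np.ones(minute.n_epochs, dtype=bool), minute.start_time)
    else:
        wear_intensity = detect_nonwear(minute, hecht_params())
        wear_ee = detect_nonwear(minute, troiano_params())
    cutsets = builtin_cutpoints()
    out: Dict[str, DailyOutcome] = {}
    for analysis in entry.analyses:
        oc = zone_minutes(minute, cutsets[analysis.cutpoints], wear_intensity,
                          min_wear_hours=min_wear_hours)
        if not entry.reports_steps:
            oc.steps = None
        if ee_sidecar is not None:
            oc.aee_kcal = ee_sidecar["aee_kcal"]
            oc.tee_kcal = ee_sidecar.get("tee_kcal")
        elif analysis.ee_method is not None:
            oc.aee_kcal = daily_aee(minute, subject, wear_ee,
                                    EnergyParams(method=analysis.ee_method,
                                                 dit_fraction=dit_fraction))
        oc.device = analysis.name(series.device)
        out[analysis.name(series.device)] = oc
    return out


def _truth_ee_sidecar(profile: TruthProfile, subject: Subject, entry: RosterEntry,
                      rng: np.random.Generator, dit_fraction: float) -> Dict[str, float]:
    """Device-reported daily EE for chest devices: truth AEE with the
    device's EE gain and reporting noise, plus its TEE via Schofield REE."""
    d = entry.device
    aee = d.ee_gain * profile.total_aee
    if d.ee_noise_sd > 0:
        aee += rng.normal(0.0, d.ee_noise_sd)
    aee = max(0.0, aee)
    tee = convert_aee_tee(aee, schofield_ree(subject), "aee_to_tee", dit_fraction)
    return {"aee_kcal": aee, "tee_kcal": tee}


# --- the full study --------------------------------------------------------

def run_validation(config: StudyConfig) -> ValidationReport:
    """Simulate (or load) the study and compute the full agreement report.

    Deterministic given ``config.seed``: all child seeds derive from it.
    """
    log_lines: List[str] = []
    rng_master = np.random.default_rng(config.seed)
    child = lambda: int(rng_master.integers(0, 2**31 - 1))  # noqa: E731

    if config.subjects_csv:
        subjects = epoch_io.read_subjects_csv(config.subjects_csv)
    else:
        subjects = simulate_subjects(config.n_subjects, child())
    log_lines.append(f"subjects: {len(subjects)}")

    # ground truth + per-device outcomes
    outcomes: Dict[str, Dict[str, DailyOutcome]] = {}
    truths: Dict[str, TruthProfile] = {}
    hetero_rng = np.random.default_rng(child())
    render_seed_rng = np.random.default_rng(child())
    for subject in subjects:
        probs = perturb_zone_probs(config.profile.zone_probs, hetero_rng,
                                   activity_sigma=config.heterogeneity_sigma)
        pconf = replace(config.profile, zone_probs=probs)
        profile = simulate_profile(subject, pconf,
                                   int(render_seed_rng.integers(0, 2**31 - 1)))
        truths[subject.id] = profile
        for entry in config.roster:
            seed = int(render_seed_rng.integers(0, 2**31 - 1))
            if entry.device.summary_only:
                oc = render_summary(profile, subject, entry.device, seed,
                                    dit_fraction=config.dit_fraction)
                outcomes.setdefault(entry.device.name, {})[subject.id] = oc
            else:
                series = render_counts(profile, entry.device, seed)
                sidecar = None
                if entry.ee_from_truth:
                    sidecar = _truth_ee_sidecar(
                        profile, subject, entry,
                        np.random.default_rng(seed + 1), config.dit_fraction)
                per_analysis = derive_epoch_outcomes(
                    series, subject, entry,
                    min_wear_hours=config.min_wear_hours,
                    dit_fraction=config.dit_fraction,
                    ee_sidecar=sidecar)
                for name, oc in per_analysis.items():
                    outcomes.setdefault(name, {})[subject.id] = oc

    subj_by_id = {s.id: s for s in subjects}
    report = build_agreement_report(
        outcomes, subj_by_id, config, log_lines)
    report.subjects = pd.DataFrame([
        {"id": s.id, "height_cm": s.height_cm, "weight_kg": s.weight_kg,
         "age_y": s.age_y, "sex": s.sex} for s in subjects
    ])
    all_ocs = [oc for per in outcomes.values() for oc in per.values()]
    report.daily_outcomes = outcomes_to_frame(all_ocs).sort_values(
        ["device", "subject_id"]).reset_index(drop=True)
    if config.outdir:
        report.write(config.outdir)
    return report


def _instrument_names(config: StudyConfig) -> Dict[str, List[str]]:
    """Map roster entries to the outcome-table instrument names they yield."""
    names = {}
    for entry in config.roster:
        if entry.device.summary_only:
            names[entry.device.name] = [entry.device.name]
        else:
            names[entry.device.name] = [a.name(entry.device.name)
                                        for a in entry.analyses]
    return names


def _outcome_value(oc: DailyOutcome, outcome: str, subject: Subject,
                   dit_fraction: float) -> Optional[float]:
    """Extract an outcome from a DailyOutcome, converting AEE↔TEE (once)
    when the instrument lacks the requested energy variable."""
    val = getattr(oc, outcome, None)
    if val is not None:
        return float(val)
    ree = schofield_ree(subject)
    if outcome == "tee_kcal" and oc.aee_kcal is not None:
        return convert_aee_tee(oc.aee_kcal, ree, "aee_to_tee", dit_fraction)
    if outcome == "aee_kcal" and oc.tee_kcal is not None:
        return convert_aee_tee(oc.tee_kcal, ree, "tee_to_aee", dit_fraction)
    return None


def build_agreement_report(outcomes: Dict[str, Dict[str, DailyOutcome]],
                           subjects: Dict[str, Subject],
                           config: StudyConfig,
                           log_lines: Optional[List[str]] = None,
                           ) -> ValidationReport:
    """Compare the test instrument against every criterion combination.

    ``outcomes`` maps instrument name → subject id → DailyOutcome.
    Subjects failing the ≥10 h wear rule on either compared instrument are
    excluded pairwise.  Steps rows are emitted once per criterion *device*
    (both axis analyses of one accelerometer count the same steps).
    """
    log_lines = log_lines if log_lines is not None else []
    test_name = config.test_entry.device.name
    test_ocs = outcomes[test_name]
    boot_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] % (2**31))

    rows, ba_rows, ss_rows = [], [], []
    seen_steps_devices = set()
    for entry in config.criterion_entries:
        for inst in _instrument_names(config)[entry.device.name]:
            crit_ocs = outcomes[inst]
            for outcome in ALL_OUTCOMES:
                if outcome == "steps":
                    if not entry.reports_steps:
                        log_lines.append(
                            f"skip steps vs {inst}: instrument reports no steps")
                        continue
                    if entry.device.name in seen_steps_devices:
                        continue  # same physical step count as the other axis
                ids, tvals, cvals = [], [], []
                for sid, toc in test_ocs.items():
                    coc = crit_ocs.get(sid)
                    if coc is None or not (toc.valid and coc.valid):
                        continue
                    tv = _outcome_value(toc, outcome, subjects[sid], config.dit_fraction)
                    cv = _outcome_value(coc, outcome, subjects[sid], config.dit_fraction)
                    if tv is None or cv is None:
                        continue
                    ids.append(sid); tvals.append(tv); cvals.append(cv)
                if len(ids) < 3:
                    log_lines.append(
                        f"skip {outcome} vs {inst}: only {len(ids)} complete pair(s)")
                    continue
                pairs = agreement.PairedOutcomes(outcome, tvals, cvals, ids)
                seed = int(boot_rng.integers(0, 2**31 - 1))
                try:
                    res = agreement.compare(pairs, n_boot=config.bootstrap, seed=seed)
                except agreement.UndefinedStatisticError as exc:
                    log_lines.append(f"skip {outcome} vs {inst}: {exc}")
                    continue
                row = {"criterion": inst, **res.to_row()}
                rows.append(row)
                for sid, tv, cv in zip(ids, tvals, cvals):
                    ba_rows.append({
                        "criterion": inst, "outcome": outcome, "subject_id": sid,
                        "test": tv, "criterion_value": cv,
                        "mean": (tv + cv) / 2.0, "diff": tv - cv,
                    })
                if outcome == "steps":
                    seen_steps_devices.add(entry.device.name)
                    sens, spec = agreement.goal_sens_spec(pairs, config.step_goal)
                    ss_rows.append({
                        "criterion": inst, "goal": config.step_goal,
                        "sensitivity": np.nan if sens is None else sens,
                        "specificity": np.nan if spec is None else spec,
                        "n": pairs.n,
                    })

    return ValidationReport(
        subjects=pd.DataFrame(),
        daily_outcomes=pd.DataFrame(),
        agreement=pd.DataFrame(rows),
        ba_data=pd.DataFrame(ba_rows),
        sens_spec=pd.DataFrame(ss_rows),
        log_lines=log_lines,
    )


# --- YAML configuration ----------------------------------------------------

def load_config(path, seed: Optional[int] = None,
                outdir: Optional[str] = None,
                bootstrap: Optional[int] = None) -> StudyConfig:
    """Build a StudyConfig from a YAML file plus CLI overrides.

    Recognised keys: ``n_subjects, seed, bootstrap, step_goal, outdir,
    subjects_csv, heterogeneity_sigma, min_wear_hours, devices``.
    ``devices`` is a mapping of roster device name → overrides
    (``cpm_gain, cpm_noise_sd, step_gain, ee_gain, force_wear, ...``).
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    roster = default_roster()
    for name, over in (raw.pop("devices", {}) or {}).items():
        entry = next((e for e in roster if e.device.name == name), None)
        if entry is None:
            raise ValueError(f"config names unknown device {name!r}")
        dev_fields = {k: v for k, v in over.items() if k != "force_wear"}
        entry.device = replace(entry.device, **dev_fields)
        if "force_wear" in over:
            entry.force_wear = bool(over["force_wear"])
    known = {"n_subjects", "seed", "bootstrap", "step_goal", "outdir",
             "subjects_csv", "heterogeneity_sigma", "min_wear_hours"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = StudyConfig(roster=roster, **raw)
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    if bootstrap is not None:
        cfg.bootstrap = bootstrap
    return cfg
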