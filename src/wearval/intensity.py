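"""Cut-point classification of 60 s epochs into physical-activity zones.

A :class:`CutPointSet` partitions the non-negative counts-per-minute (CPM)
axis into contiguous intensity zones (sedentary, light, moderate, vigorous
and — for most sets — very vigorous).  The three built-in sets are the ones
commonly used for adult free-living data:

* ``freedson_matthews_uniaxial`` — vertical-axis ActiGraph CPM,
* ``sasaki_vm3`` — triaxial ActiGraph vector-magnitude CPM,
* ``schrack_actiheart`` — chest-worn uniaxial Actiheart CPM (four zones).

Printed thresholds are integers and the intervals are closed on them
("100–1951" means [100, 1951]); classification is implemented with the zone
lower bounds so non-integer CPM produced by calibration hooks is assigned
unambiguously to the zone whose lower bound it last passed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .containers import NONWEAR, ZONES, CountSeries, DailyOutcome, ValidationError
from .preprocess import WearMask, valid_days, vector_magnitude


@dataclass(frozen=True)
class CutPointSet:
    """Ordered CPM thresholds for intensity zones.

    ``lower_bounds`` holds each zone's inclusive lower bound, starting at 0
    for sedentary; the top zone is open-ended.  ``metric`` names the CPM
    variable the set applies to.
    """

    name: str
    metric: str  # "uniaxial_cpm" | "vm_cpm" | "actiheart_cpm"
    lower_bounds: tuple  # inclusive lower bound per zone, first must be 0

    def __post_init__(self) -> None:
        lb = self.lower_bounds
        if lb[0] != 0 or any(b <= a for a, b in zip(lb, lb[1:])):
            raise ValueError("lower bounds must start at 0 and strictly increase")

    @property
    def zones(self) -> tuple:
        return ZONES[: len(self.lower_bounds)]

    def intervals(self) -> dict:
        """Zone → (low, high) closed intervals as conventionally printed
        (high is None for the open-ended top zone)."""
        out = {}
        for i, zone in enumerate(self.zones):
            lo = self.lower_bounds[i]
            hi = self.lower_bounds[i + 1] - 1 if i + 1 < len(self.lower_bounds) else None
            out[zone] = (lo, hi)
        return out


def builtin_cutpoints() -> dict:
    """The three reference cut-point sets, exactly as printed (CPM)."""
    return {
        "freedson_matthews_uniaxial": CutPointSet(
            "freedson_matthews_uniaxial", "uniaxial_cpm", (0, 100, 1952, 5725, 9499)
        ),
        "sasaki_vm3": CutPointSet(
            "sasaki_vm3", "vm_cpm", (0, 150, 2690, 6167, 9643)
        ),
        # Chest-worn set defines no very-vigorous zone: vigorous is open-ended.
        "schrack_actiheart": CutPointSet(
            "schrack_actiheart", "actiheart_cpm", (0, 11, 96, 235)
        ),
    }


def classify_epoch(cpm, cuts: CutPointSet):
    """Assign a 60 s epoch (or an array of them) to an intensity zone.

    Parameters
    ----------
    cpm : float or array
        Counts per minute, ≥ 0.
    cuts : CutPointSet

    Returns
    -------
    str or ndarray of str
        Zone name(s).
    """
    arr = np.asarray(cpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cpm must be non-negative")
    idx = np.searchsorted(np.asarray(cuts.lower_bounds, dtype=float), arr, side="right") - 1
    zones = np.asarray(cuts.zones, dtype=object)[idx]
    if np.ndim(cpm) == 0:
        return str(np.asarray(zones).item()) if np.ndim(zones) else str(zones)
    return zones


def series_cpm(series: CountSeries, cuts: CutPointSet,
               calibration: Optional[Callable] = None) -> np.ndarray:
    """Per-minute CPM of a 60 s series under the set's metric.

    ``calibration`` is an optional per-epoch CPM transform (e.g. a
    wrist-to-hip conversion); it defaults to identity because no published
    conversion exists for wrist-worn adult cut points.
    """
    if series.epoch_length != 60:
        raise ValueError("series must be reintegrated to 60 s epochs first")
    if cuts.metric == "vm_cpm":
        cpm = vector_magnitude(series)
    else:
        cpm = np.asarray(series.axis1, dtype=float)
    if calibration is not None:
        cpm = np.asarray(calibration(cpm), dtype=float)
        if np.any(cpm < 0):
            raise ValidationError("calibration produced negative CPM")
    return cpm


def zone_minutes(series: CountSeries, cuts: CutPointSet, mask: WearMask,
                 min_wear_hours: float = 10.0,
                 calibration: Optional[Callable] = None) -> DailyOutcome:
    """Aggregate one day's worn minutes into zone totals, MVPA and steps.

    Only worn minutes are counted; very-vigorous minutes are folded into
    ``vigorous_min`` (the study combined the two zones before comparison).
    The validity flag applies the ≥ 10 h wear rule.
    """
    cpm = series_cpm(series, cuts, calibration)
    if len(mask.worn) != len(cpm):
        raise ValueError("wear mask is not aligned to the series")
    zones = classify_epoch(cpm, cuts)
    worn = mask.worn
    totals = {z: float(np.sum(worn & (zones == z))) for z in cuts.zones}
    vig = totals.get("vigorous", 0.0) + totals.get("very_vigorous", 0.0)
    steps = None
    if series.steps is not None:
        steps = float(np.sum(np.asarray(series.steps)[worn]))
    wear_min = float(np.sum(worn))
    valid = bool(np.all(valid_days(mask, min_hours=min_wear_hours))) if len(worn) else False
    return DailyOutcome(
        subject_id=series.subject_id,
        device=series.device,
        date=str(series.start_time.date()),
        sedentary_min=totals.get("sedentary", 0.0),
        light_min=totals.get("light", 0.0),
        moderate_min=totals.get("moderate", 0.0),
        vigorous_min=vig,
        wear_min=wear_min,
        valid=valid,
        steps=steps,
    )
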