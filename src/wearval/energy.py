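"""Energy expenditure from activity counts and anthropometry.

Three pieces:

* ``schofield_ree`` — resting energy expenditure (REE, kcal/day) from the
  Schofield weight-based regressions by sex and adult age band;
* ``aee_per_minute`` / ``daily_aee`` — activity energy expenditure (AEE,
  kcal/min and kcal/day) from counts per minute via the two combination
  models used by commercial actigraphy software: below a CPM switch point
  the Williams work–energy equation applies, at higher CPM a linear
  regression on counts and body mass takes over.  The uniaxial combination
  pairs the Williams equation with the Freedson 1998 regression on the
  vertical axis; the triaxial combination pairs it with the Sasaki VM3
  regression on vector-magnitude CPM;
* ``convert_aee_tee`` — conversion between AEE and total energy expenditure
  (TEE) that attributes a fixed fraction of TEE (default 10%) to
  diet-induced thermogenesis (DIT):  TEE = (AEE + REE) / (1 − f).

All coefficients live in the constants tables below and each is covered by
an independently hand-computed oracle test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CountSeries, Subject
from .preprocess import WearMask, vector_magnitude

# --- constants -------------------------------------------------------------

#: Schofield REE regressions (kcal/day): sex -> [(age_lo, age_hi, slope, intercept)].
#: Adult bands; the upper age edge is inclusive, so age 30 falls in 18-30.
SCHOFIELD_KCAL = {
    "male": [
        (18.0, 30.0, 15.057, 692.2),
        (30.0, 60.0, 11.472, 873.1),
        (60.0, np.inf, 11.711, 587.7),
    ],
    "female": [
        (18.0, 30.0, 14.818, 486.6),
        (30.0, 60.0, 8.126, 845.6),
        (60.0, np.inf, 9.082, 658.5),
    ],
}

#: Williams work-energy equation: kcal/min = 0.0000191 * CPM * body mass (kg).
WILLIAMS_KCAL_PER_CPM_KG = 0.0000191

#: method -> (CPM switch point, regression slope per CPM, slope per kg, intercept).
#: Above the switch point kcal/min = b_cpm*CPM + b_kg*kg + c; at or below it
#: the Williams equation applies.
COMBINATION_MODELS = {
    "freedson_combo_1998": (1951.0, 0.00094, 0.1346, -7.37418),
    "freedson_vm3_combo_2011": (2453.0, 0.001064, 0.087512, -5.500229),
}


@dataclass(frozen=True)
class EnergyParams:
    """Energy-branch configuration: combination model, DIT fraction, REE equation."""

    method: str = "freedson_combo_1998"
    dit_fraction: float = 0.10
    ree_equation: str = "schofield"

    def __post_init__(self) -> None:
        if self.method not in COMBINATION_MODELS:
            raise ValueError(f"unknown EE method {self.method!r}")
        if not 0 <= self.dit_fraction < 1:
            raise ValueError("dit_fraction must be in [0, 1)")
        if self.ree_equation != "schofield":
            raise ValueError("only the Schofield REE equation is implemented")


# --- operations ------------------------------------------------------------

def schofield_ree(subject: Subject) -> float:
    """Resting energy expenditure (kcal/day) from weight, sex and age band."""
    for age_lo, age_hi, slope, intercept in SCHOFIELD_KCAL[subject.sex]:
        if age_lo <= subject.age_y <= age_hi:
            return slope * subject.weight_kg + intercept
    raise ValueError(f"no Schofield band for age {subject.age_y}")


def aee_per_minute(cpm, weight_kg: float, method: str = "freedson_combo_1998"):
    """Activity energy expenditure (kcal/min) for one 60 s epoch.

    Vectorized over ``cpm``.  Below or at the model's switch point the
    Williams work-energy equation applies; above it the count/body-mass
    regression.  Results are floored at zero.
    """
    if method not in COMBINATION_MODELS:
        raise ValueError(f"unknown EE method {method!r}")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    arr = np.asarray(cpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cpm must be non-negative")
    switch, b_cpm, b_kg, c = COMBINATION_MODELS[method]
    low = WILLIAMS_KCAL_PER_CPM_KG * arr * weight_kg
    high = b_cpm * arr + b_kg * weight_kg + c
    out = np.maximum(np.where(arr > switch, high, low), 0.0)
    return float(out) if np.ndim(cpm) == 0 else out


def switch_discontinuity(weight_kg: float, method: str = "freedson_combo_1998") -> float:
    """Jump (kcal/min, regression minus Williams) at the model's CPM switch
    point.  The combination models are not continuous there; this reports
    the size of the step so callers can log it."""
    switch, b_cpm, b_kg, c = COMBINATION_MODELS[method]
    low = WILLIAMS_KCAL_PER_CPM_KG * switch * weight_kg
    high = b_cpm * switch + b_kg * weight_kg + c
    return high - low


def daily_aee(series: CountSeries, subject: Subject, mask: WearMask,
              params: EnergyParams = EnergyParams()) -> float:
    """Daily AEE (kcal): sum of per-minute AEE over worn minutes.

    The triaxial combination model runs on vector-magnitude CPM, the
    uniaxial one on the vertical axis.  The mask is conventionally produced
    with the Troiano-style nonwear rule for this branch.
    """
    if series.epoch_length != 60:
        raise ValueError("daily_aee requires a series at 60 s epochs")
    if len(mask.worn) != series.n_epochs:
        raise ValueError("wear mask is not aligned to the series")
    if params.method == "freedson_vm3_combo_2011":
        cpm = vector_magnitude(series)
    else:
        cpm = np.asarray(series.axis1, dtype=float)
    per_min = aee_per_minute(cpm, subject.weight_kg, params.method)
    return float(np.sum(per_min[mask.worn]))


def convert_aee_tee(value: float, ree: float, direction: str,
                    dit_fraction: float = 0.10) -> float:
    """Convert between AEE and TEE with DIT as a fixed fraction of TEE.

    ``aee_to_tee``:  TEE = (AEE + REE) / (1 − f)
    ``tee_to_aee``:  AEE = TEE·(1 − f) − REE, floored at 0.

    The two directions are exact inverses away from the floor.
    """
    if not 0 <= dit_fraction < 1:
        raise ValueError("dit_fraction must be in [0, 1)")
    if ree <= 0:
        raise ValueError("ree must be positive")
    if value < 0:
        raise ValueError("energy value must be non-negative")
    if direction == "aee_to_tee":
        return (value + ree) / (1.0 - dit_fraction)
    if direction == "tee_to_aee":
        return max(0.0, value * (1.0 - dit_fraction) - ree)
    raise ValueError(f"unknown direction {direction!r}")
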