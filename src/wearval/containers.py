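"""Shared data containers for the device-validation pipeline.

The pipeline passes three kinds of objects between its stages:

* :class:`Subject` — anthropometry used by the resting-energy equations;
* :class:`CountSeries` — a uniform-epoch stream of activity counts (and
  optionally steps) for one subject wearing one device;
* :class:`DailyOutcome` — one subject-day's derived physical-activity
  variables (zone minutes, MVPA, steps, energy expenditure, wear time).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Intensity zones, ordered from lowest to highest intensity.
ZONES = ("sedentary", "light", "moderate", "vigorous", "very_vigorous")
#: Sentinel zone for minutes during which the device was not worn.
NONWEAR = "nonwear"
MINUTES_PER_DAY = 1440


class FormatError(ValueError):
    """A file does not parse under the requested CSV dialect."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant (e.g. negative counts)."""


@dataclass(frozen=True)
class Subject:
    """One study participant, with the anthropometry the energy equations need.

    Heights, weights and ages are constrained to the plausible adult ranges
    the study population covered; the generator truncates to the same ranges.
    """

    id: str
    height_cm: float
    weight_kg: float
    age_y: float
    sex: str  # "female" | "male"

    def __post_init__(self) -> None:
        if not 140 <= self.height_cm <= 210:
            raise ValidationError(f"height {self.height_cm} cm outside [140, 210]")
        if not 40 <= self.weight_kg <= 140:
            raise ValidationError(f"weight {self.weight_kg} kg outside [40, 140]")
        if self.age_y < 18:
            raise ValidationError(f"age {self.age_y} y below the adult minimum of 18")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(eq=False)
class CountSeries:
    """Uniform-epoch activity counts for one subject-device.

    ``axis1`` is the vertical axis; ``axis2``/``axis3`` are present only for
    triaxial devices.  ``steps`` is optional (chest devices do not export it).
    Counts are non-negative; they are floats so that calibration hooks may
    produce fractional counts, but raw device exports carry integers.
    """

    subject_id: str
    device: str
    start_time: pd.Timestamp
    epoch_length: int  # seconds
    axis1: np.ndarray
    axis2: Optional[np.ndarray] = None
    axis3: Optional[np.ndarray] = None
    steps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.epoch_length <= 0:
            raise ValidationError("epoch_length must be positive")
        self.axis1 = np.asarray(self.axis1, dtype=float)
        for name in ("axis2", "axis3", "steps"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.axis1.shape:
                    raise ValidationError(f"{name} length differs from axis1")
                setattr(self, name, arr)
        if (self.axis2 is None) != (self.axis3 is None):
            raise ValidationError("axis2 and axis3 must be given together")
        for name in ("axis1", "axis2", "axis3", "steps"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr < 0):
                raise ValidationError(f"negative values in {name}")

    # -- convenience -------------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return len(self.axis1)

    @property
    def is_triaxial(self) -> bool:
        return self.axis2 is not None

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_length / 60.0

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=f"{self.epoch_length}s"
        )

    def replace(self, **kwargs) -> "CountSeries":
        return replace(self, **kwargs)

    def __eq__(self, other) -> bool:  # arrays need value comparison
        if not isinstance(other, CountSeries):
            return NotImplemented

        def eq(a, b):
            if a is None or b is None:
                return a is b
            return np.array_equal(a, b)

        return (
            self.subject_id == other.subject_id
            and self.device == other.device
            and self.start_time == other.start_time
            and self.epoch_length == other.epoch_length
            and eq(self.axis1, other.axis1)
            and eq(self.axis2, other.axis2)
            and eq(self.axis3, other.axis3)
            and eq(self.steps, other.steps)
        )


@dataclass
class DailyOutcome:
    """One subject-day's derived physical-activity variables for one device.

    ``vigorous_min`` folds very-vigorous minutes in (the study combined the
    two before comparison), and ``mvpa_min`` is always moderate + vigorous.
    Either energy field may be absent: hip/wrist research accelerometers
    report activity energy expenditure (AEE) only, the consumer watch total
    energy expenditure (TEE) only.
    """

    subject_id: str
    device: str
    date: str
    sedentary_min: float
    light_min: float
    moderate_min: float
    vigorous_min: float
    wear_min: float
    valid: bool
    mvpa_min: float = field(default=None)  # type: ignore[assignment]
    steps: Optional[float] = None
    aee_kcal: Optional[float] = None
    tee_kcal: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mvpa_min is None:
            self.mvpa_min = self.moderate_min + self.vigorous_min
        for name in (
            "sedentary_min", "light_min", "moderate_min", "vigorous_min",
            "mvpa_min", "wear_min", "steps", "aee_kcal", "tee_kcal",
        ):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValidationError(f"{name} is negative ({val})")


def outcomes_to_frame(outcomes: list[DailyOutcome]) -> pd.DataFrame:
    """Tabulate DailyOutcome records, one row per subject-day-device."""
    cols = [
        "subject_id", "device", "date", "sedentary_min", "light_min",
        "moderate_min", "vigorous_min", "mvpa_min", "steps",
        "aee_kcal", "tee_kcal", "wear_min", "valid",
    ]
    rows = [{c: getattr(o, c) for c in cols} for o in outcomes]
    return pd.DataFrame(rows, columns=cols)
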