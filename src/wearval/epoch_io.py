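"""Reading and writing epoch-count and daily-summary CSV files.

Three epoch dialects emulate the export formats the pipeline consumes:

* ``actilife`` — a 10-line preamble (as research-accelerometer exports carry)
  followed by ``Timestamp,Axis1,Axis2,Axis3,Steps``; always triaxial with
  steps, missing axes written as 0;
* ``actiheart`` — a single header ``Timestamp,Counts``; uniaxial, no steps;
* ``generic`` — a single header ``Timestamp,axis1[,axis2,axis3][,steps]``.

All dialects use ISO-8601 local timestamps (single-day recordings, no time
zones).  Epoch length is inferred from the timestamp spacing and must be
uniform and one of 10, 15 or 60 seconds on input.

Daily summaries (consumer-watch style) are plain CSVs with one row per
subject-day; a ``rest_min`` column, if present, is ignored, matching how
the study discarded the watch's "minutes in rest" category.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    CountSeries,
    DailyOutcome,
    FormatError,
    Subject,
    ValidationError,
)

DIALECTS = ("actilife", "actiheart", "generic")
_ALLOWED_EPOCHS = (10, 15, 60)
_ACTILIFE_PREAMBLE_LINES = 10
_ACTILIFE_HEADER = ["Timestamp", "Axis1", "Axis2", "Axis3", "Steps"]
_ACTIHEART_HEADER = ["Timestamp", "Counts"]

SUMMARY_REQUIRED = [
    "subject_id", "date", "sedentary_min", "light_min",
    "moderate_min", "vigorous_min", "steps", "tee_kcal",
]


def _infer_epoch(ts: pd.DatetimeIndex, dialect: str) -> int:
    if len(ts) < 2:
        return 60  # a 0/1-row file carries no spacing; default epoch
    deltas = np.diff(ts.asi8) / 1e9
    if not np.all(deltas == deltas[0]):
        raise ValidationError(f"non-uniform timestamp spacing in {dialect} file")
    epoch = float(deltas[0])
    if epoch not in _ALLOWED_EPOCHS:
        raise ValidationError(
            f"epoch length {epoch}s not one of {_ALLOWED_EPOCHS} in {dialect} file"
        )
    return int(epoch)


def _check_nonneg(df: pd.DataFrame, cols, what: str) -> None:
    for c in cols:
        if (df[c] < 0).any():
            raise ValidationError(f"negative {what} in column {c}")


def read_epoch_csv(path, dialect: str, subject_id: str = "",
                   device: str = "") -> CountSeries:
    """Parse an epoch-count CSV under the named dialect.

    Raises :class:`FormatError` (naming the dialect) on a malformed header
    and :class:`ValidationError` on negative counts or non-uniform
    timestamps.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        if dialect == "actilife":
            for _ in range(_ACTILIFE_PREAMBLE_LINES):
                if not fh.readline():
                    raise FormatError("actilife: preamble shorter than 10 lines")
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{dialect}: missing header row") from None
        rows = list(reader)

    if dialect == "actilife":
        if header != _ACTILIFE_HEADER:
            raise FormatError(f"actilife: expected header {_ACTILIFE_HEADER}, got {header}")
        cols = ["axis1", "axis2", "axis3", "steps"]
    elif dialect == "actiheart":
        if header != _ACTIHEART_HEADER:
            raise FormatError(
                f"actiheart: expected header {_ACTIHEART_HEADER} (uniaxial, no steps), "
                f"got {header}"
            )
        cols = ["axis1"]
    else:  # generic
        if not header or header[0] != "Timestamp":
            raise FormatError(f"generic: first column must be Timestamp, got {header}")
        body = header[1:]
        valid_layouts = (
            ["axis1"], ["axis1", "steps"],
            ["axis1", "axis2", "axis3"], ["axis1", "axis2", "axis3", "steps"],
        )
        if body not in valid_layouts:
            raise FormatError(f"generic: unsupported column layout {body}")
        cols = body

    df = pd.DataFrame(rows, columns=["Timestamp"] + cols) if rows else pd.DataFrame(
        columns=["Timestamp"] + cols
    )
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(df["Timestamp"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{dialect}: unparseable timestamps: {exc}") from None
    for c in cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    _check_nonneg(df, cols, "counts")
    epoch = _infer_epoch(ts, dialect)

    def col(name):
        return df[name].to_numpy(dtype=float) if name in cols else None

    return CountSeries(
        subject_id=subject_id or path.stem,
        device=device or dialect,
        start_time=ts[0] if len(ts) else pd.Timestamp("2000-01-01"),
        epoch_length=epoch,
        axis1=col("axis1") if rows else np.array([]),
        axis2=col("axis2"),
        axis3=col("axis3"),
        steps=col("steps"),
    )


def write_epoch_csv(series: CountSeries, path, dialect: str) -> Path:
    """Write a CountSeries under the named dialect; inverse of read.

    The actilife dialect always writes all three axes and steps (zeros for
    fields the series lacks); actiheart writes the vertical axis only.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ts = series.timestamps().strftime("%Y-%m-%dT%H:%M:%S")
    n = series.n_epochs

    def fmt(arr):
        a = np.zeros(n) if arr is None else np.asarray(arr, dtype=float)
        return [f"{v:.0f}" if float(v).is_integer() else repr(float(v)) for v in a]

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "actilife":
            fh.write(_actilife_preamble(series))
            w.writerow(_ACTILIFE_HEADER)
            for row in zip(ts, fmt(series.axis1), fmt(series.axis2),
                           fmt(series.axis3), fmt(series.steps)):
                w.writerow(row)
        elif dialect == "actiheart":
            if series.is_triaxial:
                raise FormatError("actiheart: dialect is uniaxial; series has 3 axes")
            w.writerow(_ACTIHEART_HEADER)
            for row in zip(ts, fmt(series.axis1)):
                w.writerow(row)
        else:
            header = ["Timestamp", "axis1"]
            cols = [fmt(series.axis1)]
            if series.is_triaxial:
                header += ["axis2", "axis3"]
                cols += [fmt(series.axis2), fmt(series.axis3)]
            if series.steps is not None:
                header.append("steps")
                cols.append(fmt(series.steps))
            w.writerow(header)
            for row in zip(ts, *cols):
                w.writerow(row)
    return path


def _actilife_preamble(series: CountSeries) -> str:
    """Ten metadata lines in the spirit of research-software exports."""
    lines = [
        "--- Data File Created By Export ---",
        f"Serial Number: {series.device}",
        f"Start Time {series.start_time.strftime('%H:%M:%S')}",
        f"Start Date {series.start_time.strftime('%d/%m/%Y')}",
        f"Epoch Period (hh:mm:ss) 00:00:{series.epoch_length:02d}",
        "Download Time 00:00:00",
        "Download Date 01/01/2000",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.0     Mode = 61",
        "--------------------------------------------------",
    ]
    return "\n".join(lines) + "\n"


# --- daily summaries -------------------------------------------------------

def read_summary_csv(path, device: str = "") -> list:
    """Parse consumer-watch style daily summaries into DailyOutcome records.

    Required columns: ``subject_id,date,sedentary_min,light_min,
    moderate_min,vigorous_min,steps,tee_kcal``.  ``mvpa_min`` is recomputed
    as moderate + vigorous; a ``rest_min`` column is ignored.  Optional
    ``wear_min`` / ``valid`` / ``aee_kcal`` / ``device`` columns are carried
    through when present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"summary file missing required column(s): {missing}")
    num_cols = [c for c in df.columns
                if c not in ("subject_id", "date", "device", "valid")]
    _check_nonneg(df, [c for c in num_cols if c != "valid"], "minutes/steps/kcal")
    outcomes = []
    for _, row in df.iterrows():
        outcomes.append(DailyOutcome(
            subject_id=str(row["subject_id"]),
            device=str(row["device"]) if "device" in df.columns else (device or path.stem),
            date=str(row["date"]),
            sedentary_min=float(row["sedentary_min"]),
            light_min=float(row["light_min"]),
            moderate_min=float(row["moderate_min"]),
            vigorous_min=float(row["vigorous_min"]),
            wear_min=float(row["wear_min"]) if "wear_min" in df.columns else 1440.0,
            valid=bool(row["valid"]) if "valid" in df.columns else True,
            steps=float(row["steps"]),
            aee_kcal=float(row["aee_kcal"]) if "aee_kcal" in df.columns
            and pd.notna(row["aee_kcal"]) else None,
            tee_kcal=float(row["tee_kcal"]),
        ))
    return outcomes


def write_summary_csv(outcomes: list, path) -> Path:
    rows = []
    for o in outcomes:
        rows.append({
            "subject_id": o.subject_id, "device": o.device, "date": o.date,
            "sedentary_min": o.sedentary_min, "light_min": o.light_min,
            "moderate_min": o.moderate_min, "vigorous_min": o.vigorous_min,
            "mvpa_min": o.mvpa_min, "steps": o.steps,
            "aee_kcal": o.aee_kcal, "tee_kcal": o.tee_kcal,
            "wear_min": o.wear_min, "valid": o.valid,
        })
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    return Path(path)


# --- subject tables --------------------------------------------------------

def read_subjects_csv(path) -> list:
    df = pd.read_csv(Path(path))
    required = ["id", "height_cm", "weight_kg", "age_y", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"subject table missing column(s): {missing}")
    return [
        Subject(str(r["id"]), float(r["height_cm"]), float(r["weight_kg"]),
                float(r["age_y"]), str(r["sex"]))
        for _, r in df.iterrows()
    ]


def write_subjects_csv(subjects: list, path) -> Path:
    pd.DataFrame([
        {"id": s.id, "height_cm": s.height_cm, "weight_kg": s.weight_kg,
         "age_y": s.age_y, "sex": s.sex}
        for s in subjects
    ]).to_csv(Path(path), index=False)
    return Path(path)
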