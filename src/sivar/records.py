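"""Clinical-style patient records and their CSV dialect.

A record holds one patient's blood-glucose measurements (mmol/L), insulin
administration (U/h bolus-equivalent rates) and carbohydrate delivery (g/h),
plus outcome metadata. Times are minutes on a common clock with ICU admission
as the natural origin.

On-disk layout (UTF-8, header rows required):

* data CSV, long format: ``patient_id, signal, time_min, value`` with
  ``signal`` in {bg, insulin, nutrition}; insulin in U/h, nutrition in g/h.
* metadata CSV: ``patient_id, outcome, admission_time, therapy_start,
  diabetic_status``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .icing import InputSchedule, ModelInputError, PiecewiseConstant

#: unit conversions into model units
U_PER_H_TO_MU_PER_MIN = 1000.0 / 60.0
MMOL_PER_G_GLUCOSE = 1000.0 / 180.156
G_PER_H_TO_MMOL_PER_MIN = MMOL_PER_G_GLUCOSE / 60.0

OUTCOMES = ("survivor", "non-survivor")
DIABETIC_STATUSES = ("none", "type1", "type2")


@dataclass
class PatientRecord:
    """One patient's time series with outcome metadata (clinical units)."""

    patient_id: str
    outcome: str
    admission_time: float
    therapy_start: float
    bg_times: np.ndarray          # min
    bg_values: np.ndarray         # mmol/L
    insulin_times: np.ndarray     # min, step starts
    insulin_rates: np.ndarray     # U/h
    nutrition_times: np.ndarray   # min, step starts
    nutrition_rates: np.ndarray   # g/h
    diabetic_status: str = "none"

    def __post_init__(self) -> None:
        for name in ("bg_times", "bg_values", "insulin_times", "insulin_rates",
                     "nutrition_times", "nutrition_rates"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.outcome not in OUTCOMES:
            raise ModelInputError(
                f"patient {self.patient_id}: outcome must be one of {OUTCOMES}")
        if self.diabetic_status not in DIABETIC_STATUSES:
            raise ModelInputError(
                f"patient {self.patient_id}: diabetic_status must be one of {DIABETIC_STATUSES}")
        if self.therapy_start < self.admission_time:
            raise ModelInputError(
                f"patient {self.patient_id}: therapy_start before admission_time")
        if self.bg_times.size != self.bg_values.size:
            raise ModelInputError(f"patient {self.patient_id}: bg arrays differ in length")
        if self.bg_times.size and np.any(np.diff(self.bg_times) <= 0):
            raise ModelInputError(f"patient {self.patient_id}: bg times not strictly increasing")
        if np.any(self.bg_values <= 0):
            raise ModelInputError(f"patient {self.patient_id}: bg values must be > 0")
        for nm in ("insulin", "nutrition"):
            t = getattr(self, f"{nm}_times")
            r = getattr(self, f"{nm}_rates")
            if t.size != r.size or t.size == 0:
                raise ModelInputError(
                    f"patient {self.patient_id}: {nm} schedule empty or ragged")
            if np.any(np.diff(t) <= 0):
                raise ModelInputError(
                    f"patient {self.patient_id}: {nm} times not strictly increasing")
            if np.any(r < 0):
                raise ModelInputError(f"patient {self.patient_id}: {nm} rates must be >= 0")

    # -- model-unit views ---------------------------------------------------
    def input_schedule(self) -> InputSchedule:
        """Schedules converted to model units (u_ex mU/min, P mmol/min)."""
        return InputSchedule(
            u_ex=PiecewiseConstant(self.insulin_times,
                                   self.insulin_rates * U_PER_H_TO_MU_PER_MIN),
            P=PiecewiseConstant(self.nutrition_times,
                                self.nutrition_rates * G_PER_H_TO_MMOL_PER_MIN),
        )

    @property
    def bg_span(self) -> tuple[float, float]:
        if self.bg_times.size < 2:
            raise ModelInputError(f"patient {self.patient_id}: fewer than 2 BG measurements")
        return float(self.bg_times[0]), float(self.bg_times[-1])

    def therapy_coverage_hours(self) -> float:
        """Hours of BG-covered therapy data from therapy start."""
        if self.bg_times.size == 0:
            return 0.0
        return max(0.0, (float(self.bg_times[-1]) - self.therapy_start) / 60.0)


# -- CSV dialect ------------------------------------------------------------

def records_to_frames(records: Iterable[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    data_rows, meta_rows = [], []
    for r in records:
        for t, v in zip(r.bg_times, r.bg_values):
            data_rows.append((r.patient_id, "bg", t, v))
        for t, v in zip(r.insulin_times, r.insulin_rates):
            data_rows.append((r.patient_id, "insulin", t, v))
        for t, v in zip(r.nutrition_times, r.nutrition_rates):
            data_rows.append((r.patient_id, "nutrition", t, v))
        meta_rows.append((r.patient_id, r.outcome, r.admission_time,
                          r.therapy_start, r.diabetic_status))
    data = pd.DataFrame(data_rows, columns=["patient_id", "signal", "time_min", "value"])
    meta = pd.DataFrame(meta_rows, columns=["patient_id", "outcome", "admission_time",
                                            "therapy_start", "diabetic_status"])
    return data, meta


def frames_to_records(data: pd.DataFrame, meta: pd.DataFrame) -> list[PatientRecord]:
    need_data = {"patient_id", "signal", "time_min", "value"}
    need_meta = {"patient_id", "outcome", "admission_time", "therapy_start"}
    if not need_data <= set(data.columns):
        raise ModelInputError(f"data CSV must have columns {sorted(need_data)}")
    if not need_meta <= set(meta.columns):
        raise ModelInputError(f"metadata CSV must have columns {sorted(need_meta)}")
    records = []
    grouped = dict(tuple(data.groupby("patient_id", sort=False)))
    for row in meta.itertuples(index=False):
        pid = str(row.patient_id)
        for f in ("outcome", "admission_time", "therapy_start"):
            val = getattr(row, f)
            if pd.isna(val):
                raise ModelInputError(f"patient {pid}: missing metadata field {f}")
        g = grouped.get(row.patient_id)
        if g is None:
            raise ModelInputError(f"patient {pid}: no time-series data")
        parts = {}
        for sig in ("bg", "insulin", "nutrition"):
            sub = g[g["signal"] == sig].sort_values("time_min")
            parts[sig] = (sub["time_min"].to_numpy(float), sub["value"].to_numpy(float))
        records.append(PatientRecord(
            patient_id=pid,
            outcome=str(row.outcome),
            admission_time=float(row.admission_time),
            therapy_start=float(row.therapy_start),
            bg_times=parts["bg"][0], bg_values=parts["bg"][1],
            insulin_times=parts["insulin"][0], insulin_rates=parts["insulin"][1],
            nutrition_times=parts["nutrition"][0], nutrition_rates=parts["nutrition"][1],
            diabetic_status=str(getattr(row, "diabetic_status", "none")),
        ))
    return records


def write_records_csv(records: Sequence[PatientRecord], data_path: str | Path,
                      meta_path: str | Path) -> None:
    data, meta = records_to_frames(records)
    data.to_csv(data_path, index=False, float_format="%.10g")
    meta.to_csv(meta_path, index=False, float_format="%.10g")


def read_records_csv(data_path: str | Path, meta_path: str | Path) -> list[PatientRecord]:
    return frames_to_records(pd.read_csv(data_path), pd.read_csv(meta_path))
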