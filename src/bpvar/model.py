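"""Cohort data model and long-format tabular I/O.

A cohort is a set of :class:`PatientRecord` objects, each holding a pair of
monitoring sources (``continuous`` 1-min finger-cuff series and
``intermittent`` scheduled arm-cuff readings) for the three pressure channels
(SBP, DBP, MBP), a clinical covariate block and the binary haemorrhagic
transformation outcome.  The interchange format is a tidy long CSV, one row
per sample, plus a one-row-per-patient clinical CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("continuous", "intermittent")
CHANNELS = ("SBP", "DBP", "MBP")

#: Clinically defined absolute exceedance thresholds (mmHg) per channel.
THRESHOLDS = {"SBP": 185.0, "DBP": 110.0, "MBP": 130.0}

RECORDING_COLUMNS = ["patient_id", "source", "channel", "time_min", "value_mmHg"]
CLINICAL_COLUMNS = [
    "patient_id",
    "nihss_category",
    "admission_mbp",
    "time_to_reperfusion_h",
    "iv_thrombolysis",
    "periprocedural_antithrombotic",
    "ht_outcome",
]

#: Default admission-NIHSS bin edges: scores 0-3 / 4-14 / 15-20 / >20.
NIHSS_BIN_UPPER = (3, 14, 20)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent rows in an input table."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open analysis window ``[start_min, end_min)`` on the minutes-
    since-reperfusion axis."""

    label: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not self.end_min > self.start_min:
            raise ValueError("window must have positive length")

    @property
    def length_min(self) -> float:
        return self.end_min - self.start_min

    def contains(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return (t >= self.start_min) & (t < self.end_min)


WINDOWS = {
    "P1": AnalysisWindow("P1", 0.0, 480.0),
    "P2": AnalysisWindow("P2", 480.0, 960.0),
    "P3": AnalysisWindow("P3", 960.0, 1440.0),
    "FULL24": AnalysisWindow("FULL24", 0.0, 1440.0),
}


def intermittent_schedule() -> np.ndarray:
    """Scheduled arm-cuff reading times (minutes since reperfusion).

    Every 15 min for the first 2 h, every 30 min for the next 6 h, every
    60 min thereafter; the day is half-open so the t=1440 slot is excluded,
    leaving 36 slots.
    """
    return np.concatenate(
        [
            np.arange(0, 121, 15, dtype=float),
            np.arange(150, 481, 30, dtype=float),
            np.arange(540, 1440, 60, dtype=float),
        ]
    )


def scheduled_slots_in(window: AnalysisWindow) -> int:
    """Number of scheduled intermittent readings falling in *window*."""
    return int(window.contains(intermittent_schedule()).sum())


def derive_mbp(sbp, dbp):
    """Mean blood pressure from systolic and diastolic: SBP/3 + 2*DBP/3.

    Accepts scalars or arrays. Raises ``ValueError`` where ``sbp < dbp``
    (non-NaN); NaNs propagate.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (sbp < dbp) & ~np.isnan(sbp) & ~np.isnan(dbp)
    if np.any(bad):
        raise ValueError("derive_mbp: sbp < dbp")
    out = sbp / 3.0 + 2.0 * dbp / 3.0
    return float(out) if out.ndim == 0 else out


def categorize_nihss(score, bin_upper=NIHSS_BIN_UPPER) -> int:
    """Map a raw admission NIHSS score to its ordinal category (0..3)."""
    return int(np.searchsorted(np.asarray(bin_upper, dtype=float), score, side="left"))


@dataclass
class BPSeries:
    """A time-stamped, validity-masked pressure series for one
    (source, channel) pair.

    ``valid`` marks usable samples (observed or imputed); ``imputed`` flags
    the subset of valid samples that were filled by gap imputation rather
    than observed.
    """

    source: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    imputed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.valid)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        n = self.times.size
        if self.values.size != n or self.valid.size != n or self.imputed.size != n:
            raise ValueError("times, values, valid, imputed must align")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.imputed & ~self.valid):
            raise ValueError("imputed samples must be valid")

    @property
    def observed(self) -> np.ndarray:
        """Mask of samples that are valid and not imputed."""
        return self.valid & ~self.imputed

    def in_window(self, window: AnalysisWindow) -> "BPSeries":
        m = window.contains(self.times)
        return BPSeries(
            self.source,
            self.channel,
            self.times[m],
            self.values[m],
            self.valid[m],
            self.imputed[m],
        )

    def copy(self) -> "BPSeries":
        return BPSeries(
            self.source,
            self.channel,
            self.times.copy(),
            self.values.copy(),
            self.valid.copy(),
            self.imputed.copy(),
        )


@dataclass
class Covariates:
    """Clinical adjustment covariates for the multivariable models."""

    nihss_category: Optional[int]
    admission_mbp: Optional[float]
    time_to_reperfusion_h: Optional[float]
    iv_thrombolysis: Optional[bool]
    periprocedural_antithrombotic: Optional[bool]

    def __post_init__(self) -> None:
        if self.nihss_category is not None and self.nihss_category not in (0, 1, 2, 3):
            raise ValueError("nihss_category must be one of 0..3")
        if self.admission_mbp is not None and not self.admission_mbp > 0:
            raise ValueError("admission_mbp must be positive")
        if self.time_to_reperfusion_h is not None and self.time_to_reperfusion_h < 0:
            raise ValueError("time_to_reperfusion_h must be non-negative")

    def is_complete(self) -> bool:
        return all(
            v is not None
            for v in (
                self.nihss_category,
                self.admission_mbp,
                self.time_to_reperfusion_h,
                self.iv_thrombolysis,
                self.periprocedural_antithrombotic,
            )
        )


@dataclass
class PatientRecord:
    """One subject: identifier, covariates, outcome and the six series."""

    patient_id: str
    covariates: Covariates
    ht_outcome: Optional[bool]
    series: dict = field(default_factory=dict)  # (source, channel) -> BPSeries

    def get_series(self, source: str, channel: str) -> BPSeries:
        return self.series[(source, channel)]

    def has_series(self, source: str, channel: str) -> bool:
        return (source, channel) in self.series

    def with_series(self, new: dict) -> "PatientRecord":
        merged = dict(self.series)
        merged.update(new)
        return replace(self, series=merged)


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_cohort`: what was read, coerced, dropped."""

    n_patients: int
    recordings_only: list
    clinical_only: list
    coerced_cells: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"loaded {self.n_patients} patients; "
            f"{self.coerced_cells} unparsable sample cells coerced to missing; "
            f"recordings-only: {self.recordings_only}; clinical-only: {self.clinical_only}"
        )


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column {col!r}")


def _parse_bool(x) -> Optional[bool]:
    if pd.isna(x):
        return None
    return bool(int(x))


def load_cohort(recordings_path, clinical_path):
    """Read the recordings and clinical CSVs into PatientRecords.

    Returns ``(records, report)`` where *records* is an ``{patient_id:
    PatientRecord}`` dict restricted to patients present in both files and
    *report* is a :class:`LoadReport` listing coercions and one-sided
    patients.  Unparsable pressure cells become ``valid=False`` samples.
    Intermittent (and, if absent, continuous) MBP is derived from SBP/DBP.
    """
    rec = pd.read_csv(recordings_path, dtype={"patient_id": str})
    clin = pd.read_csv(clinical_path, dtype={"patient_id": str})
    _require_columns(rec, RECORDING_COLUMNS, "recordings")
    _require_columns(clin, CLINICAL_COLUMNS, "clinical")

    dup = rec.duplicated(subset=["patient_id", "source", "channel", "time_min"])
    if dup.any():
        row = rec[dup].iloc[0]
        raise IntegrityError(
            "duplicate sample for "
            f"({row.patient_id}, {row.source}, {row.channel}, t={row.time_min})"
        )
    if clin["patient_id"].duplicated().any():
        raise IntegrityError("duplicate patient_id in clinical file")

    values = pd.to_numeric(rec["value_mmHg"], errors="coerce")
    coerced = int((values.isna() & rec["value_mmHg"].notna()).sum())
    if coerced:
        logger.warning("coerced %d unparsable value_mmHg cells to missing", coerced)
    rec = rec.assign(value_mmHg=values)

    rec_ids = set(rec["patient_id"])
    clin_ids = set(clin["patient_id"])
    both = rec_ids & clin_ids
    report = LoadReport(
        n_patients=len(both),
        recordings_only=sorted(rec_ids - clin_ids),
        clinical_only=sorted(clin_ids - rec_ids),
        coerced_cells=coerced,
    )

    clin = clin.set_index("patient_id")
    records: dict[str, PatientRecord] = {}
    for pid, g in rec.groupby("patient_id", sort=True):
        if pid not in both:
            continue
        series: dict = {}
        for (source, channel), sg in g.groupby(["source", "channel"], sort=True):
            sg = sg.sort_values("time_min")
            v = sg["value_mmHg"].to_numpy(dtype=float)
            series[(source, channel)] = BPSeries(
                source=source,
                channel=channel,
                times=sg["time_min"].to_numpy(dtype=float),
                values=v,
                valid=~np.isnan(v),
            )
        for source in SOURCES:
            _ensure_mbp(series, source)
        row = clin.loc[pid]
        cov = Covariates(
            nihss_category=None if pd.isna(row["nihss_category"]) else int(row["nihss_category"]),
            admission_mbp=None if pd.isna(row["admission_mbp"]) else float(row["admission_mbp"]),
            time_to_reperfusion_h=(
                None if pd.isna(row["time_to_reperfusion_h"]) else float(row["time_to_reperfusion_h"])
            ),
            iv_thrombolysis=_parse_bool(row["iv_thrombolysis"]),
            periprocedural_antithrombotic=_parse_bool(row["periprocedural_antithrombotic"]),
        )
        records[pid] = PatientRecord(
            patient_id=pid,
            covariates=cov,
            ht_outcome=_parse_bool(row["ht_outcome"]),
            series=series,
        )
    return records, report


def _ensure_mbp(series: dict, source: str) -> None:
    """Derive the MBP series from SBP/DBP when it was not recorded."""
    if (source, "MBP") in series:
        return
    if (source, "SBP") not in series or (source, "DBP") not in series:
        return
    sbp = series[(source, "SBP")]
    dbp = series[(source, "DBP")]
    if sbp.times.size != dbp.times.size or not np.array_equal(sbp.times, dbp.times):
        raise IntegrityError(f"{source}: SBP/DBP time axes differ, cannot derive MBP")
    both = sbp.valid & dbp.valid
    vals = np.full(sbp.times.size, np.nan)
    ok = both & ~(sbp.values < dbp.values)
    vals[ok] = sbp.values[ok] / 3.0 + 2.0 * dbp.values[ok] / 3.0
    series[(source, "MBP")] = BPSeries(source, "MBP", sbp.times.copy(), vals, ok)


def cohort_to_frames(records: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize records back to the (recordings, clinical) long frames.

    Only observed (non-imputed) samples are written; masked samples keep an
    empty value cell so the round trip is lossless at the schema level.
    """
    rows = []
    crows = []
    for pid in sorted(records):
        r = records[pid]
        for (source, channel) in sorted(r.series):
            s = r.series[(source, channel)]
            obs = s.observed
            vals = np.where(obs, s.values, np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "source": source,
                        "channel": channel,
                        "time_min": s.times,
                        "value_mmHg": vals,
                    }
                )
            )
        c = r.covariates
        crows.append(
            {
                "patient_id": pid,
                "nihss_category": c.nihss_category,
                "admission_mbp": c.admission_mbp,
                "time_to_reperfusion_h": c.time_to_reperfusion_h,
                "iv_thrombolysis": None if c.iv_thrombolysis is None else int(c.iv_thrombolysis),
                "periprocedural_antithrombotic": (
                    None if c.periprocedural_antithrombotic is None else int(c.periprocedural_antithrombotic)
                ),
                "ht_outcome": None if r.ht_outcome is None else int(r.ht_outcome),
            }
        )
    recordings = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=RECORDING_COLUMNS)
    clinical = pd.DataFrame(crows, columns=CLINICAL_COLUMNS)
    return recordings, clinical


def write_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as CSV with stable column order.

    Refuses empty input (no file is created). Values round-trip exactly
    through the text representation.
    """
    if not isinstance(rows, pd.DataFrame):
        raise TypeError("write_table expects a DataFrame")
    if rows.empty:
        raise ValueError("refusing to write an empty table")
    rows.to_csv(path, index=False)
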