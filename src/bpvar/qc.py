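"""Cleaning, gap imputation and per-period eligibility for BP recordings.

The continuous channel goes through a deterministic three-stage artefact
mask (plausibility bounds, step-change limit, rolling-median deviation),
then short gaps (< ``max_impute_gap_min``) are filled from a mask-normalised
Gaussian-smoothed version of the valid signal.  Eligibility per analysis
window applies, in order: outcome/covariate availability, a minimum valid
fraction for both sources, and a minimum contiguous run of valid minutes.
Masking never alters stored values — samples are only flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .model import (
    CHANNELS,
    AnalysisWindow,
    BPSeries,
    PatientRecord,
    scheduled_slots_in,
)

DAY_MIN = 1440

REASONS = (
    "missing_outcome",
    "missing_covariates",
    "insufficient_intermittent",
    "insufficient_continuous",
    "no_contiguous_window",
)


@dataclass
class QCConfig:
    bounds: dict = field(
        default_factory=lambda: {
            "SBP": (40.0, 300.0),
            "DBP": (20.0, 200.0),
            "MBP": (30.0, 250.0),
        }
    )
    max_step_mmhg: float = 40.0
    rolling_window_min: int = 15
    rolling_mad_mult: float = 5.0
    mad_floor_mmhg: float = 1.0
    max_impute_gap_min: int = 5  # gaps strictly shorter than this are imputed
    min_contiguous_min: int = 128
    min_valid_fraction: float = 0.30
    gaussian_sigma_min: float = 2.5

    def __post_init__(self) -> None:
        if not self.max_impute_gap_min < self.min_contiguous_min:
            raise ValueError("max imputable gap must be shorter than min contiguous window")
        if not 0.0 < self.min_valid_fraction < 1.0:
            raise ValueError("min_valid_fraction must lie in (0, 1)")


@dataclass
class FlagCounts:
    """Per-rule artefact flag counts for one series."""

    bounds: int = 0
    step: int = 0
    rolling: int = 0

    @property
    def total(self) -> int:
        return self.bounds + self.step + self.rolling


@dataclass
class EligibilityReport:
    patient_id: str
    window: str
    eligible: bool
    reasons: list

    def __post_init__(self) -> None:
        assert self.eligible == (len(self.reasons) == 0)


def average_to_minute(raw: BPSeries, day_min: int = DAY_MIN) -> BPSeries:
    """Average raw samples onto the regular 1-min grid [0, day_min).

    Each output minute is the mean of the valid raw samples in [t, t+1);
    minutes without valid samples are marked invalid.
    """
    grid = np.arange(day_min, dtype=float)
    values = np.full(day_min, np.nan)
    valid = np.zeros(day_min, dtype=bool)
    if raw.times.size:
        m = raw.valid & (raw.times >= 0) & (raw.times < day_min) & ~np.isnan(raw.values)
        idx = np.floor(raw.times[m]).astype(int)
        counts = np.bincount(idx, minlength=day_min)
        sums = np.bincount(idx, weights=raw.values[m], minlength=day_min)
        has = counts > 0
        values[has] = sums[has] / counts[has]
        valid = has
    return BPSeries(raw.source, raw.channel, grid, values, valid)


def _assert_minute_grid(series: BPSeries) -> None:
    if series.times.size == 0 or not np.allclose(np.diff(series.times), 1.0):
        raise ValueError("series must be on a regular 1-min grid")


def remove_artifacts(series: BPSeries, cfg: QCConfig) -> tuple[BPSeries, FlagCounts]:
    """Mask implausible samples; values are never altered.

    Stage order: plausibility bounds, then step-change vs the last accepted
    sample within each contiguous run, then rolling-median/MAD deviation.
    """
    _assert_minute_grid(series)
    out = series.copy()
    counts = FlagCounts()
    v = out.values
    valid = out.valid.copy()

    lo, hi = cfg.bounds[series.channel]
    bad = valid & ((v < lo) | (v > hi))
    counts.bounds = int(bad.sum())
    valid &= ~bad

    # step rule: flag a sample jumping > max_step from the previous-minute
    # accepted sample; once flagged, the next sample's reference is > 1 min
    # away, so it is accepted (spikes don't cascade onto the recovery sample)
    step_bad = np.zeros_like(valid)
    diff = np.abs(np.diff(v))
    cand = np.flatnonzero(valid[1:] & valid[:-1] & (diff > cfg.max_step_mmhg)) + 1
    for i in cand:
        if not step_bad[i - 1]:
            step_bad[i] = True
    counts.step = int(step_bad.sum())
    valid &= ~step_bad

    x = pd.Series(np.where(valid, v, np.nan))
    roll = x.rolling(cfg.rolling_window_min, center=True, min_periods=5)
    med = roll.median()
    resid = (x - med).abs()
    mad = resid.rolling(cfg.rolling_window_min, center=True, min_periods=5).median()
    thresh = cfg.rolling_mad_mult * np.maximum(mad.to_numpy(), cfg.mad_floor_mmhg)
    roll_bad = valid & (resid.to_numpy() > thresh)
    counts.rolling = int(np.nansum(roll_bad))
    valid &= ~roll_bad

    out.valid = valid
    out.imputed = out.imputed & valid
    return out, counts


def impute_short_gaps(series: BPSeries, cfg: QCConfig) -> BPSeries:
    """Fill invalid runs strictly shorter than the gap limit.

    Fill values come from a Gaussian-smoothed version of the valid signal
    (mask-normalised weights, sigma ``gaussian_sigma_min``); filled samples
    are marked valid with ``imputed=True``.  Longer runs are untouched.
    """
    _assert_minute_grid(series)
    out = series.copy()
    if not out.valid.any():
        warnings.warn("impute_short_gaps: series has no valid samples", stacklevel=2)
        return out
    m = out.valid.astype(float)
    num = gaussian_filter1d(np.where(out.valid, out.values, 0.0), cfg.gaussian_sigma_min)
    den = gaussian_filter1d(m, cfg.gaussian_sigma_min)
    smooth = np.divide(num, den, out=np.full_like(num, np.nan), where=den > 1e-12)

    for start, stop in _invalid_runs(out.valid):
        if stop - start >= cfg.max_impute_gap_min:
            continue
        fill = smooth[start:stop]
        ok = ~np.isnan(fill)
        idx = np.arange(start, stop)[ok]
        out.values[idx] = fill[ok]
        out.valid[idx] = True
        out.imputed[idx] = True
    return out


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal invalid runs."""
    inv = ~valid
    if not inv.any():
        return
    padded = np.concatenate([[False], inv, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    yield from zip(starts, stops)


def _valid_runs(valid: np.ndarray):
    padded = np.concatenate([[False], valid, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))


def longest_contiguous_window(series: BPSeries, window: AnalysisWindow, cfg: QCConfig):
    """Longest run of consecutive valid minutes within *window*.

    Returns ``(start_min, end_min)`` (half-open, earliest on ties) or
    ``None`` if the longest run is shorter than the configured minimum.
    """
    sub = series.in_window(window)
    if sub.times.size == 0:
        return None
    best = None
    best_len = 0
    for start, stop in _valid_runs(sub.valid):
        if stop - start > best_len:
            best_len = stop - start
            best = (float(sub.times[start]), float(sub.times[stop - 1] + 1))
    if best is None or best_len < cfg.min_contiguous_min:
        return None
    return best


def continuous_valid_fraction(record: PatientRecord, window: AnalysisWindow) -> float:
    """Min across channels of observed-valid minutes / window length."""
    fracs = []
    for ch in CHANNELS:
        s = record.get_series("continuous", ch).in_window(window)
        fracs.append(float(s.observed.sum()) / window.length_min)
    return min(fracs)


def intermittent_valid_fraction(record: PatientRecord, window: AnalysisWindow) -> float:
    """Min across channels of valid readings / scheduled slots in window."""
    slots = scheduled_slots_in(window)
    if slots == 0:
        return 0.0
    fracs = []
    for ch in CHANNELS:
        s = record.get_series("intermittent", ch).in_window(window)
        fracs.append(float(s.valid.sum()) / slots)
    return min(fracs)


def assess_eligibility(record: PatientRecord, window: AnalysisWindow, cfg: QCConfig) -> EligibilityReport:
    """Apply the three inclusion criteria for one window.

    (i) outcome and complete covariates available; (ii) valid fraction of at
    least ``min_valid_fraction`` in both sources; (iii) a contiguous run of
    at least ``min_contiguous_min`` valid continuous minutes (post
    imputation) in every channel.
    """
    reasons = []
    if record.ht_outcome is None:
        reasons.append("missing_outcome")
    if not record.covariates.is_complete():
        reasons.append("missing_covariates")
    if intermittent_valid_fraction(record, window) < cfg.min_valid_fraction:
        reasons.append("insufficient_intermittent")
    if continuous_valid_fraction(record, window) < cfg.min_valid_fraction:
        reasons.append("insufficient_continuous")
    else:
        spans = [
            longest_contiguous_window(record.get_series("continuous", ch), window, cfg)
            for ch in CHANNELS
        ]
        if any(sp is None for sp in spans):
            reasons.append("no_contiguous_window")
    return EligibilityReport(record.patient_id, window.label, len(reasons) == 0, reasons)


def preprocess_record(record: PatientRecord, cfg: QCConfig) -> tuple[PatientRecord, dict]:
    """Run the full QC chain on a record's continuous channels.

    Continuous series are regularised to the 1-min grid, artefact-masked and
    gap-imputed; intermittent series only get the plausibility-bounds mask.
    Returns the cleaned record and per-series flag counts.
    """
    new = {}
    counts = {}
    for ch in CHANNELS:
        if record.has_series("continuous", ch):
            s = average_to_minute(record.get_series("continuous", ch))
            s, c = remove_artifacts(s, cfg)
            s = impute_short_gaps(s, cfg)
            new[("continuous", ch)] = s
            counts[("continuous", ch)] = c
        if record.has_series("intermittent", ch):
            s = record.get_series("intermittent", ch).copy()
            lo, hi = cfg.bounds[ch]
            with np.errstate(invalid="ignore"):
                s.valid = s.valid & (s.values >= lo) & (s.values <= hi)
            new[("intermittent", ch)] = s
    return record.with_series(new), counts


def eligibility_frame(reports: list[EligibilityReport]) -> pd.DataFrame:
    """Tabulate eligibility reports, one row per patient x window."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in reports],
            "window": [r.window for r in reports],
            "eligible": [int(r.eligible) for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )
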