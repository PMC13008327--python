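"""Per-patient variability features: dispersion statistics and wavelet-band
normalised energies.

Statistical features are computed on observed (non-imputed) valid samples
only; wavelet energies use the imputed contiguous span so the decomposition
sees a gapless signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wavelets
from .model import CHANNELS, THRESHOLDS, AnalysisWindow, BPSeries, PatientRecord
from .qc import QCConfig, longest_contiguous_window

STAT_NAMES = ("mean", "max", "range", "sd", "cv", "prop_gt_thr")

#: Supported level->label conventions for the five reported bands.
BAND_CONVENTIONS = ("finest-2-4min", "finest-1-2min")


@dataclass
class WaveletConfig:
    family: str = "db8"
    levels: int = 5
    #: "finest-2-4min" labels detail level j by its physical period range
    #: [2^j, 2^(j+1)] min on the 1-min grid; "finest-1-2min" shifts the
    #: ladder down one octave so the finest level carries the 1-2 min label.
    band_convention: str = "finest-2-4min"

    def __post_init__(self) -> None:
        if self.band_convention not in BAND_CONVENTIONS:
            raise ValueError(f"unknown band convention {self.band_convention!r}")
        if self.family not in wavelets.FAMILIES:
            raise ValueError(f"unknown wavelet family {self.family!r}")

    def band_labels(self) -> list[str]:
        finest = 2.0 if self.band_convention == "finest-2-4min" else 1.0
        bands = wavelets.level_period_bands(self.levels, finest_period=finest)
        return [f"{int(lo)}_{int(hi)}" for lo, hi in bands]


@dataclass
class StatFeatures:
    mean: float
    maximum: float
    range: float
    sd: float
    cv: float
    prop_above_threshold: float
    n_obs: int


@dataclass
class WaveletEnergies:
    energies: dict  # label -> mmHg^2/min
    approx_energy: float
    span_min: int
    family: str
    convention: str


def stat_features(series: BPSeries, window: AnalysisWindow, threshold: float):
    """Dispersion statistics over observed valid samples in *window*.

    Returns ``None`` when fewer than 2 observed samples are available. The
    SD is the sample (n-1) standard deviation; CV is 100*sd/mean (NaN for
    non-positive mean); the exceedance proportion is in percent.
    """
    sub = series.in_window(window)
    x = sub.values[sub.observed]
    if x.size < 2:
        return None
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return StatFeatures(
        mean=mean,
        maximum=float(np.max(x)),
        range=float(np.max(x) - np.min(x)),
        sd=sd,
        cv=100.0 * sd / mean if mean > 0 else float("nan"),
        prop_above_threshold=100.0 * float(np.sum(x > threshold)) / x.size,
        n_obs=int(x.size),
    )


def wavelet_band_energies(series: BPSeries, span, cfg: WaveletConfig, min_span: int = 128) -> WaveletEnergies:
    """Normalised band energies of a contiguous valid span of a 1-min series.

    *span* is a half-open ``(start_min, end_min)`` pair; every sample inside
    must be valid (observed or imputed).  The mean is subtracted and the
    span truncated to the largest dyadic-compatible prefix before the
    transform; energies are sums of squared detail coefficients divided by
    the span length used, in mmHg^2/min.
    """
    start, end = span
    if end - start < min_span:
        raise ValueError(f"span of {end - start:.0f} min is shorter than {min_span} min")
    m = (series.times >= start) & (series.times < end)
    if not np.all(series.valid[m]):
        raise ValueError("span contains invalid samples")
    x = series.values[m]
    det, app, n_used = wavelets.band_energies(x, cfg.levels, cfg.family)
    labels = cfg.band_labels()
    return WaveletEnergies(
        energies={lab: float(e) for lab, e in zip(labels, det)},
        approx_energy=float(app),
        span_min=int(n_used),
        family=cfg.family,
        convention=cfg.band_convention,
    )


def _stat_columns(src: str, ch: str) -> dict:
    thr = int(THRESHOLDS[ch])
    return {
        "mean": f"{src}_{ch}_mean_mmHg",
        "max": f"{src}_{ch}_max_mmHg",
        "range": f"{src}_{ch}_range_mmHg",
        "sd": f"{src}_{ch}_sd_mmHg",
        "cv": f"{src}_{ch}_cv_pct",
        "prop_gt_thr": f"{src}_{ch}_prop_gt{thr}_pct",
    }


def feature_columns(wav_cfg: WaveletConfig) -> list[str]:
    """Stable column order of the per-window feature table."""
    cols = []
    for src in ("cont", "int"):
        for ch in CHANNELS:
            cols.extend(_stat_columns(src, ch).values())
    for ch in CHANNELS:
        for lab in wav_cfg.band_labels():
            cols.append(f"cont_{ch}_wav_{lab}_mmHg2_per_min")
    return cols


def patient_features(
    record: PatientRecord,
    window: AnalysisWindow,
    qc_cfg: QCConfig,
    wav_cfg: WaveletConfig,
) -> dict:
    """One feature row (dict of column -> value) for a preprocessed record."""
    row: dict = {}
    for src, prefix in (("continuous", "cont"), ("intermittent", "int")):
        for ch in CHANNELS:
            cols = _stat_columns(prefix, ch)
            sf = (
                stat_features(record.get_series(src, ch), window, THRESHOLDS[ch])
                if record.has_series(src, ch)
                else None
            )
            if sf is None:
                row.update({c: np.nan for c in cols.values()})
            else:
                row[cols["mean"]] = sf.mean
                row[cols["max"]] = sf.maximum
                row[cols["range"]] = sf.range
                row[cols["sd"]] = sf.sd
                row[cols["cv"]] = sf.cv
                row[cols["prop_gt_thr"]] = sf.prop_above_threshold
    for ch in CHANNELS:
        labels = wav_cfg.band_labels()
        cols = [f"cont_{ch}_wav_{lab}_mmHg2_per_min" for lab in labels]
        span = (
            longest_contiguous_window(record.get_series("continuous", ch), window, qc_cfg)
            if record.has_series("continuous", ch)
            else None
        )
        if span is None:
            row.update({c: np.nan for c in cols})
        else:
            we = wavelet_band_energies(
                record.get_series("continuous", ch), span, wav_cfg, qc_cfg.min_contiguous_min
            )
            row.update({c: we.energies[lab] for c, lab in zip(cols, labels)})
    return row


def build_feature_table(
    records: dict,
    window: AnalysisWindow,
    qc_cfg: QCConfig,
    wav_cfg: WaveletConfig,
) -> pd.DataFrame:
    """Feature table (one row per eligible patient) for one window.

    *records* maps patient_id to preprocessed, eligible PatientRecords.
    Unavailable cells (fewer than 2 observed samples, or no qualifying
    contiguous span) are NaN; the row is retained.
    """
    if not records:
        raise ValueError("no eligible patients for this window")
    rows = {
        pid: patient_features(rec, window, qc_cfg, wav_cfg)
        for pid, rec in sorted(records.items())
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df[feature_columns(wav_cfg)]
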