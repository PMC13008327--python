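"""Synthetic cohort generator.

Each patient's latent state is a baseline pressure, a pulse-pressure offset
and one oscillation amplitude per period band; the 24-h continuous MBP trace
is baseline + slow drift + band-limited random-phase sinusoid mixtures +
white noise, with artefact spikes and a time-increasing missingness process
layered on top.  Intermittent readings subsample the clean signal on the
15/30/60-min schedule with additive cuff noise.  The binary outcome follows
a logistic mechanism in the latent sub-32-min oscillation energy, so the
generator's analytic band energies provide an exact estimand for recovery
tests.  One global seed expands to per-patient substreams, making each
patient reproducible independently of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .model import (
    BPSeries,
    Covariates,
    PatientRecord,
    cohort_to_frames,
    derive_mbp,
    intermittent_schedule,
)

DAY_MIN = 1440

#: Generator period bands (minutes); the first four are the "short"
#: (sub-32-min) bands that drive the outcome mechanism.
BANDS = ((2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, 32.0), (32.0, 64.0))
N_SHORT = 4

#: Keep sinusoid periods away from band edges so the analytic per-band
#: energy is a tight target for the wavelet decomposition.
BAND_EDGE_MARGIN = 1.15
SINUSOIDS_PER_BAND = 3


@dataclass
class SimParams:
    n_patients: int = 200
    ht_prevalence: float = 0.29
    seed: int = 0

    # continuous-signal structure
    baseline_mbp_median: float = 100.0
    baseline_mbp_log_sd: float = 0.12
    drift_amp_mmhg: float = 6.0
    band_amp_mmhg: tuple = (2.0, 2.5, 3.0, 3.5, 4.0)
    amp_log_sd: float = 0.4
    noise_sd: float = 2.0
    pulse_pressure_mmhg: float = 45.0
    pulse_pressure_sd: float = 8.0
    pulse_pressure_jitter_sd: float = 2.0

    # corruption processes
    spike_rate_per_h: float = 0.5
    spike_mag_mmhg: float = 60.0
    miss_base: float = 0.02
    miss_slope: float = 0.25  # per-min missing prob = base + slope * t/1440
    gap_rate_per_h: float = 0.15
    gap_mean_min: float = 8.0

    # intermittent protocol
    cuff_noise_sd: float = 4.0
    cuff_miss_prob: float = 0.05

    # outcome mechanism
    log_or_per_sd: float = 0.0  # logistic slope on standardized latent short-band energy
    ht_amp_ratio: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)  # per-band multiplier for HT patients

    # covariate margins (Table-1-like)
    nihss_probs: tuple = (0.09, 0.46, 0.27, 0.18)
    admission_mbp_log_sd: float = 0.12
    ttr_mean_h: float = 6.0
    ttr_sd_h: float = 5.3
    p_iv_thrombolysis: float = 0.55
    p_periproc_antithrombotic: float = 0.42

    def __post_init__(self) -> None:
        if not 0.0 < self.ht_prevalence < 1.0:
            raise ValueError("ht_prevalence must lie in (0, 1)")
        if len(self.band_amp_mmhg) != len(BANDS) or len(self.ht_amp_ratio) != len(BANDS):
            raise ValueError(f"need {len(BANDS)} per-band amplitudes/ratios")
        for v in (*self.band_amp_mmhg, *self.ht_amp_ratio, self.noise_sd,
                  self.spike_rate_per_h, self.cuff_noise_sd, self.drift_amp_mmhg):
            if v < 0:
                raise ValueError("amplitudes, sds and rates must be non-negative")


def analytic_band_energy(amp: float) -> float:
    """Mean power (mmHg^2/min on a 1-min grid) of a band component with
    total sinusoid amplitude budget *amp*: sum of squared-amplitude/2."""
    return amp * amp / 2.0


def _patient_streams(seed: int, n: int):
    """Two independent substreams (latent, series) per patient."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [c.spawn(2) for c in children]


def simulate_latent(params: SimParams) -> pd.DataFrame:
    """Draw latent states, covariates and outcomes without any series.

    Returns the ground-truth table: per-band amplitudes (after the HT
    amplitude ratio), the standardized latent short-band energy ``z`` used
    by the logistic mechanism, the linear predictor and outcome.
    """
    streams = _patient_streams(params.seed, params.n_patients)
    rows = []
    for i, (latent_ss, _) in enumerate(streams):
        rng = np.random.default_rng(latent_ss)
        amps = np.array(params.band_amp_mmhg) * np.exp(
            rng.normal(0.0, params.amp_log_sd, size=len(BANDS))
        )
        rows.append(
            {
                "patient_id": f"S{i:05d}",
                "baseline_mbp": float(np.exp(rng.normal(np.log(params.baseline_mbp_median), params.baseline_mbp_log_sd))),
                "pulse_pressure": float(max(20.0, rng.normal(params.pulse_pressure_mmhg, params.pulse_pressure_sd))),
                **{f"amp_band{j+1}": float(a) for j, a in enumerate(amps)},
                "nihss_category": int(rng.choice(4, p=np.asarray(params.nihss_probs) / np.sum(params.nihss_probs))),
                "admission_mbp": float(np.exp(rng.normal(np.log(100.0), params.admission_mbp_log_sd))),
                "time_to_reperfusion_h": float(rng.gamma(
                    (params.ttr_mean_h / params.ttr_sd_h) ** 2,
                    params.ttr_sd_h**2 / params.ttr_mean_h,
                )),
                "iv_thrombolysis": int(rng.random() < params.p_iv_thrombolysis),
                "periprocedural_antithrombotic": int(rng.random() < params.p_periproc_antithrombotic),
                "u_outcome": float(rng.random()),
            }
        )
    truth = pd.DataFrame(rows).set_index("patient_id")

    amp_cols = [f"amp_band{j+1}" for j in range(len(BANDS))]
    short_energy = sum(
        analytic_band_energy(truth[amp_cols[j]].to_numpy()) for j in range(N_SHORT)
    )
    sd = short_energy.std(ddof=1) if len(truth) > 1 else 0.0
    z = (short_energy - short_energy.mean()) / (sd if sd > 0 else 1.0)
    beta = params.log_or_per_sd
    if beta == 0.0:
        alpha = float(logit(params.ht_prevalence))
    else:
        alpha = brentq(
            lambda a: expit(a + beta * z).mean() - params.ht_prevalence, -30.0, 30.0
        )
    eta = alpha + beta * z
    y = (truth["u_outcome"].to_numpy() < expit(eta)).astype(int)

    ratio = np.asarray(params.ht_amp_ratio)
    for j, col in enumerate(amp_cols):
        truth[col] = truth[col].to_numpy() * np.where(y == 1, ratio[j], 1.0)
    truth["latent_short_energy"] = short_energy  # pre-ratio mechanism input
    truth["z_short"] = z
    truth["eta"] = eta
    truth["p_ht"] = expit(eta)
    truth["ht_outcome"] = y
    for j, col in enumerate(amp_cols):
        truth[f"true_energy_band{j+1}"] = analytic_band_energy(truth[col].to_numpy())
    return truth.drop(columns=["u_outcome"])


def _band_component(rng, amp: float, lo: float, hi: float, t: np.ndarray) -> np.ndarray:
    """Random-phase sinusoid mixture with total variance amp^2/2."""
    a = amp / np.sqrt(SINUSOIDS_PER_BAND)
    periods = np.exp(rng.uniform(np.log(lo * BAND_EDGE_MARGIN), np.log(hi / BAND_EDGE_MARGIN), SINUSOIDS_PER_BAND))
    phases = rng.uniform(0.0, 2.0 * np.pi, SINUSOIDS_PER_BAND)
    return (a * np.sin(2.0 * np.pi * t[:, None] / periods + phases)).sum(axis=1)


def simulate_continuous(params: SimParams, latent: pd.Series, series_seed) -> tuple[dict, dict]:
    """24-h continuous series triple for one patient.

    Returns ``(series, clean)`` where *series* maps channel to the recorded
    BPSeries (spikes injected, wear-off missingness applied) and *clean*
    holds the artefact-free SBP/DBP/MBP arrays used as ground truth for the
    intermittent protocol.
    """
    rng = np.random.default_rng(series_seed)
    t = np.arange(DAY_MIN, dtype=float)

    mbp = np.full(DAY_MIN, latent["baseline_mbp"])
    mbp = mbp + params.drift_amp_mmhg * np.sin(2.0 * np.pi * t / DAY_MIN + rng.uniform(0, 2 * np.pi))
    for j, (lo, hi) in enumerate(BANDS):
        mbp = mbp + _band_component(rng, latent[f"amp_band{j+1}"], lo, hi, t)
    if params.noise_sd > 0:
        mbp = mbp + rng.normal(0.0, params.noise_sd, DAY_MIN)

    pp = latent["pulse_pressure"] + (
        rng.normal(0.0, params.pulse_pressure_jitter_sd, DAY_MIN)
        if params.pulse_pressure_jitter_sd > 0
        else 0.0
    )
    clean = {"MBP": mbp, "SBP": mbp + 2.0 * pp / 3.0, "DBP": mbp - pp / 3.0}

    rec_mbp = mbp.copy()
    n_spikes = rng.poisson(params.spike_rate_per_h * 24.0) if params.spike_rate_per_h > 0 else 0
    if n_spikes:
        pos = rng.integers(0, DAY_MIN, n_spikes)
        mag = params.spike_mag_mmhg * (0.8 + 0.4 * rng.random(n_spikes))
        sign = rng.choice([-1.0, 1.0], n_spikes)
        np.add.at(rec_mbp, pos, sign * mag)

    missing = rng.random(DAY_MIN) < (params.miss_base + params.miss_slope * t / DAY_MIN)
    n_gaps = rng.poisson(params.gap_rate_per_h * 24.0) if params.gap_rate_per_h > 0 else 0
    for _ in range(n_gaps):
        start = int(rng.integers(0, DAY_MIN))
        length = int(rng.geometric(1.0 / params.gap_mean_min))
        missing[start : start + length] = True

    recorded = {"MBP": rec_mbp, "SBP": rec_mbp + 2.0 * pp / 3.0, "DBP": rec_mbp - pp / 3.0}
    series = {}
    for ch, arr in recorded.items():
        vals = np.where(missing, np.nan, arr)
        series[ch] = BPSeries("continuous", ch, t.copy(), vals, ~missing)
    return series, clean


def simulate_intermittent(clean: dict, params: SimParams, rng) -> dict:
    """Scheduled cuff readings from the clean continuous truth.

    SBP/DBP readings are the truth at each slot plus independent cuff
    noise; the cuff MBP is derived from them with the SBP/3 + 2*DBP/3
    formula.  Slots go missing jointly across channels.
    """
    sched = intermittent_schedule()
    idx = sched.astype(int)
    miss = rng.random(sched.size) < params.cuff_miss_prob
    sbp = clean["SBP"][idx] + rng.normal(0.0, params.cuff_noise_sd, sched.size)
    dbp = clean["DBP"][idx] + rng.normal(0.0, params.cuff_noise_sd, sched.size)
    # a noisy DBP draw can cross its SBP partner; clamp to keep the pair sane
    dbp = np.minimum(dbp, sbp)
    mbp = derive_mbp(sbp, dbp)
    out = {}
    for ch, arr in (("SBP", sbp), ("DBP", dbp), ("MBP", mbp)):
        vals = np.where(miss, np.nan, arr)
        out[ch] = BPSeries("intermittent", ch, sched.copy(), vals, ~miss)
    return out


def simulate_cohort(params: SimParams, with_series: bool = True):
    """Generate a full cohort.

    Returns ``(records, truth)``; with ``with_series=False`` only the
    latent ground-truth table is produced and *records* is empty (fast path
    for estimator-recovery studies).
    """
    truth = simulate_latent(params)
    records: dict[str, PatientRecord] = {}
    if with_series:
        streams = _patient_streams(params.seed, params.n_patients)
        for i, pid in enumerate(truth.index):
            series_rng_seed = streams[i][1]
            rng = np.random.default_rng(series_rng_seed)
            cont, clean = simulate_continuous(params, truth.loc[pid], rng)
            inter = simulate_intermittent(clean, params, rng)
            series = {("continuous", ch): s for ch, s in cont.items()}
            series.update({("intermittent", ch): s for ch, s in inter.items()})
            row = truth.loc[pid]
            records[pid] = PatientRecord(
                patient_id=pid,
                covariates=Covariates(
                    nihss_category=int(row["nihss_category"]),
                    admission_mbp=float(row["admission_mbp"]),
                    time_to_reperfusion_h=float(row["time_to_reperfusion_h"]),
                    iv_thrombolysis=bool(row["iv_thrombolysis"]),
                    periprocedural_antithrombotic=bool(row["periprocedural_antithrombotic"]),
                ),
                ht_outcome=bool(row["ht_outcome"]),
                series=series,
            )
    return records, truth


def write_cohort_csv(records: dict, recordings_path, clinical_path) -> None:
    """Emit the recordings/clinical CSV pair consumed by ``load_cohort``."""
    recordings, clinical = cohort_to_frames(records)
    recordings.to_csv(recordings_path, index=False)
    clinical.to_csv(clinical_path, index=False)
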