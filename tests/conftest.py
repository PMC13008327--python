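import numpy as np
import pytest

from bpvar.model import (
    WINDOWS,
    BPSeries,
    Covariates,
    PatientRecord,
    derive_mbp,
    intermittent_schedule,
)

DAY = 1440


def minute_series(values, valid=None, channel="MBP", source="continuous", imputed=None):
    """Continuous 1-min-grid series over the full day from a value array."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if valid is None:
        valid = ~np.isnan(values)
    return BPSeries(source, channel, np.arange(n, dtype=float), values, valid, imputed)


def full_day(value=100.0):
    return minute_series(np.full(DAY, float(value)))


def complete_covariates(**kw):
    base = dict(
        nihss_category=1,
        admission_mbp=100.0,
        time_to_reperfusion_h=6.0,
        iv_thrombolysis=True,
        periprocedural_antithrombotic=False,
    )
    base.update(kw)
    return Covariates(**base)


def full_intermittent(sbp=120.0, dbp=70.0):
    """Fully valid intermittent triple on the scheduled slots."""
    t = intermittent_schedule()
    n = t.size
    out = {}
    for ch, v in (("SBP", sbp), ("DBP", dbp), ("MBP", derive_mbp(sbp, dbp))):
        out[("intermittent", ch)] = BPSeries(
            "intermittent", ch, t.copy(), np.full(n, float(v)), np.ones(n, bool)
        )
    return out


def make_record(pid="P1", cont_valid=None, ht_outcome=True, covariates=None,
                inter_series=None, cont_value=100.0):
    """Record with flat continuous channels (validity mask shared) and a
    fully valid intermittent triple unless overridden."""
    series = {}
    for ch in ("SBP", "DBP", "MBP"):
        base = {"SBP": cont_value + 40, "DBP": cont_value - 20, "MBP": cont_value}[ch]
        vals = np.full(DAY, float(base))
        valid = np.ones(DAY, bool) if cont_valid is None else np.asarray(cont_valid, bool).copy()
        vals[~valid] = np.nan
        series[("continuous", ch)] = minute_series(vals, valid, channel=ch)
    series.update(full_intermittent() if inter_series is None else inter_series)
    return PatientRecord(
        patient_id=pid,
        covariates=complete_covariates() if covariates is None else covariates,
        ht_outcome=ht_outcome,
        series=series,
    )


@pytest.fixture(scope="session")
def p1():
    return WINDOWS["P1"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
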