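import numpy as np
import pytest

from bpvar.model import WINDOWS, BPSeries
from bpvar.qc import (
    QCConfig,
    assess_eligibility,
    average_to_minute,
    impute_short_gaps,
    longest_contiguous_window,
    preprocess_record,
    remove_artifacts,
)

from conftest import DAY, complete_covariates, full_day, make_record, minute_series


@pytest.fixture
def cfg():
    return QCConfig()


class TestAverageToMinute:
    def test_mean_of_two_samples(self):
        raw = BPSeries("continuous", "SBP", [7.2, 7.8], [118.0, 122.0], [True, True])
        out = average_to_minute(raw)
        assert out.values[7] == pytest.approx(120.0)
        assert out.valid[7]

    def test_empty_minute_invalid(self):
        raw = BPSeries("continuous", "SBP", [7.2], [118.0], [True])
        out = average_to_minute(raw)
        assert not out.valid[6]
        assert out.valid.sum() == 1

    def test_already_one_minute_identity(self):
        vals = 100 + np.sin(np.arange(DAY) / 50.0)
        out = average_to_minute(minute_series(vals))
        assert np.allclose(out.values, vals)
        assert out.valid.all()

    def test_empty_input(self):
        raw = BPSeries("continuous", "SBP", [], [], [])
        out = average_to_minute(raw)
        assert out.times.size == DAY and not out.valid.any()


def _mad_oracle_flags(values, valid, window=15, mult=5.0, floor=1.0, min_periods=5):
    """Brute-force rolling median/MAD deviation rule."""
    n = values.size
    half = window // 2
    x = np.where(valid, values, np.nan)
    flags = np.zeros(n, bool)
    for i in range(n):
        seg = x[max(0, i - half): i + half + 1]
        seg = seg[~np.isnan(seg)]
        if seg.size < min_periods:
            continue
        med = np.median(seg)
        resid_seg = x[max(0, i - half): i + half + 1]
        resid = np.abs(resid_seg - med)
        resid = resid[~np.isnan(resid)]
        if resid.size < min_periods:
            continue
        mad = np.median(resid)
        if valid[i] and abs(values[i] - med) > mult * max(mad, floor):
            flags[i] = True
    return flags


class TestRemoveArtifacts:
    def test_bound_violation_masked(self, cfg):
        vals = np.full(DAY, 120.0)
        vals[100] = 350.0
        s = minute_series(vals, channel="SBP")
        out, counts = remove_artifacts(s, cfg)
        assert not out.valid[100]
        assert counts.bounds == 1
        assert out.values[100] == 350.0  # value untouched, only masked

    def test_clean_sinusoid_unflagged(self, cfg):
        t = np.arange(DAY)
        s = minute_series(120 + 15 * np.sin(2 * np.pi * t / 120.0), channel="SBP")
        out, counts = remove_artifacts(s, cfg)
        assert counts.total == 0
        assert out.valid.all()

    def test_spike_caught_by_rolling_rule_vs_mad_oracle(self):
        # step rule disabled so the rolling rule does the work
        cfg = QCConfig(max_step_mmhg=1e9)
        vals = np.full(DAY, 100.0) + np.sin(np.arange(DAY) / 30.0)  # avoid zero-MAD ties
        vals[700] += 60.0
        s = minute_series(vals, channel="SBP")
        out, counts = remove_artifacts(s, cfg)
        expected = _mad_oracle_flags(vals, np.ones(DAY, bool))
        assert expected[700]
        assert not out.valid[700]
        assert np.array_equal(~out.valid, expected)
        assert counts.rolling == expected.sum()

    def test_step_rule_flags_spike_not_recovery(self, cfg):
        vals = np.full(DAY, 100.0)
        vals[50] = 160.0  # +60 then back down
        s = minute_series(vals, channel="SBP")
        out, counts = remove_artifacts(s, cfg)
        assert not out.valid[50]
        assert out.valid[51]  # recovery sample survives
        assert counts.step >= 1

    def test_counts_conserve_samples(self, cfg, rng):
        vals = 100 + rng.normal(0, 3, DAY)
        vals[rng.integers(0, DAY, 20)] += 80
        s = minute_series(vals, channel="MBP")
        out, _ = remove_artifacts(s, cfg)
        assert out.times.size == s.times.size
        assert np.array_equal(out.values, s.values)  # never altered


def _gaussian_conv_oracle(values, valid, sigma):
    """Independent discrete Gaussian convolution with mask normalisation."""
    radius = int(4 * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    v = np.where(valid, values, 0.0)
    m = valid.astype(float)
    pad = lambda a: np.pad(a, radius, mode="reflect")
    num = np.convolve(pad(v), k, mode="same")[radius:-radius]
    den = np.convolve(pad(m), k, mode="same")[radius:-radius]
    return num / den


class TestImputeShortGaps:
    def test_three_min_gap_in_ramp(self, cfg):
        vals = np.linspace(80, 120, DAY)
        valid = np.ones(DAY, bool)
        valid[200:203] = False
        s = minute_series(np.where(valid, vals, np.nan), valid)
        out = impute_short_gaps(s, cfg)
        assert out.valid[200:203].all() and out.imputed[200:203].all()
        lo, hi = vals[199], vals[203]
        assert np.all((out.values[200:203] > lo) & (out.values[200:203] < hi))
        oracle = _gaussian_conv_oracle(np.where(valid, vals, 0), valid, cfg.gaussian_sigma_min)
        assert np.allclose(out.values[200:203], oracle[200:203], rtol=1e-6)

    @pytest.mark.parametrize("gap", [5, 10])
    def test_long_gap_untouched(self, cfg, gap):
        valid = np.ones(DAY, bool)
        valid[300:300 + gap] = False
        s = minute_series(np.where(valid, 100.0, np.nan), valid)
        out = impute_short_gaps(s, cfg)
        assert not out.valid[300:300 + gap].any()

    def test_gapless_identity(self, cfg):
        s = full_day(110.0)
        out = impute_short_gaps(s, cfg)
        assert np.array_equal(out.values, s.values)
        assert out.valid.all() and not out.imputed.any()

    def test_all_invalid_warns(self, cfg):
        s = minute_series(np.full(DAY, np.nan), np.zeros(DAY, bool))
        with pytest.warns(UserWarning):
            out = impute_short_gaps(s, cfg)
        assert not out.valid.any()

    def test_observed_count_unchanged(self, cfg, rng):
        valid = rng.random(DAY) > 0.1
        vals = np.where(valid, 100 + rng.normal(0, 5, DAY), np.nan)
        s = minute_series(vals, valid)
        out = impute_short_gaps(s, cfg)
        assert out.observed.sum() == s.observed.sum()
        assert (out.valid & ~s.valid).sum() == out.imputed.sum()


class TestLongestContiguousWindow:
    def _series_with_runs(self, runs):
        valid = np.zeros(DAY, bool)
        for start, length in runs:
            valid[start:start + length] = True
        return minute_series(np.where(valid, 100.0, np.nan), valid)

    def test_picks_longer_run(self, cfg):
        s = self._series_with_runs([(10, 100), (200, 140)])
        assert longest_contiguous_window(s, WINDOWS["P1"], cfg) == (200.0, 340.0)

    def test_127_is_none(self, cfg):
        s = self._series_with_runs([(0, 127)])
        assert longest_contiguous_window(s, WINDOWS["P1"], cfg) is None

    def test_128_boundary(self, cfg):
        s = self._series_with_runs([(0, 128)])
        assert longest_contiguous_window(s, WINDOWS["P1"], cfg) == (0.0, 128.0)

    def test_fully_valid_period(self, cfg):
        s = full_day()
        assert longest_contiguous_window(s, WINDOWS["P2"], cfg) == (480.0, 960.0)

    def test_tie_broken_earliest(self, cfg):
        s = self._series_with_runs([(0, 130), (200, 130)])
        assert longest_contiguous_window(s, WINDOWS["P1"], cfg) == (0.0, 130.0)


class TestEligibility:
    def test_insufficient_continuous(self, cfg, p1):
        valid = np.zeros(DAY, bool)
        valid[:96] = True  # 20% of P1
        rec = make_record(cont_valid=valid)
        rep = assess_eligibility(rec, p1, cfg)
        assert not rep.eligible
        assert rep.reasons == ["insufficient_continuous"]

    def test_missing_outcome(self, cfg, p1):
        rec = make_record(ht_outcome=None)
        rep = assess_eligibility(rec, p1, cfg)
        assert rep.reasons == ["missing_outcome"]

    def test_missing_covariates(self, cfg, p1):
        rec = make_record(covariates=complete_covariates(admission_mbp=None))
        rep = assess_eligibility(rec, p1, cfg)
        assert rep.reasons == ["missing_covariates"]

    def test_fully_observed_eligible(self, cfg, p1):
        rep = assess_eligibility(make_record(), p1, cfg)
        assert rep.eligible and rep.reasons == []

    def test_no_contiguous_window(self, cfg, p1):
        valid = np.zeros(DAY, bool)
        valid[0:127] = True
        valid[240:281] = True  # 35% valid total but longest run 127
        rec = make_record(cont_valid=valid)
        rep = assess_eligibility(rec, p1, cfg)
        assert rep.reasons == ["no_contiguous_window"]

    def test_insufficient_intermittent(self, cfg, p1):
        inter = {}
        rec = make_record()
        for key, s in rec.series.items():
            if key[0] == "intermittent":
                s = s.copy()
                s.valid[:] = False
                s.valid[:3] = True  # 3/20 scheduled in P1
                inter[key] = s
        rec = rec.with_series(inter)
        rep = assess_eligibility(rec, p1, cfg)
        assert rep.reasons == ["insufficient_intermittent"]

    def test_monotone_in_valid_samples(self, cfg, p1, rng):
        valid = rng.random(DAY) > 0.6
        rec = make_record(cont_valid=valid)
        base = assess_eligibility(rec, p1, cfg)
        more = valid.copy()
        more[rng.random(DAY) > 0.5] = True
        rec2 = make_record(cont_valid=more)
        rep2 = assess_eligibility(rec2, p1, cfg)
        if base.eligible:
            assert rep2.eligible


class TestPreprocessRecord:
    def test_chain_conserves_and_flags(self, cfg, rng):
        vals = 100 + 5 * np.sin(np.arange(DAY) / 60.0) + rng.normal(0, 1.5, DAY)
        spikes = rng.choice(DAY, 10, replace=False)
        vals[spikes] += 90
        valid = np.ones(DAY, bool)
        valid[600:603] = False
        series = {}
        for ch, off in (("SBP", 40), ("DBP", -20), ("MBP", 0)):
            v = vals + off
            v[~valid] = np.nan
            series[("continuous", ch)] = minute_series(v, valid, channel=ch)
        rec = make_record()
        rec = rec.with_series(series)
        clean, counts = preprocess_record(rec, cfg)
        for ch in ("SBP", "DBP", "MBP"):
            s = clean.get_series("continuous", ch)
            assert s.times.size == DAY
            # spikes masked (possibly re-imputed); observed spike values gone
            assert not s.observed[spikes].any()
            # short gap filled
            assert s.valid[600:603].all() and s.imputed[600:603].all()

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            QCConfig(max_impute_gap_min=200)
        with pytest.raises(ValueError):
            QCConfig(min_valid_fraction=1.5)
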