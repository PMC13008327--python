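# bpvar

Short-timescale blood-pressure variability analysis for paired continuous
(1-min finger-cuff) and intermittent (scheduled arm-cuff) recordings during
the first 24 h after endovascular thrombectomy, and its association with
haemorrhagic transformation (HT).

The package implements the full analysis chain:

1. **Data model & I/O** (`bpvar.model`) — tidy long-format recordings CSV
   (`patient_id,source,channel,time_min,value_mmHg`) plus a clinical CSV
   (covariates + binary HT outcome); MBP derivation (`SBP/3 + 2·DBP/3`);
   the 15/30/60-min intermittent schedule.
2. **QC & eligibility** (`bpvar.qc`) — 1-min averaging, a three-stage
   artefact mask (plausibility bounds, step-change limit, rolling
   median/MAD), Gaussian-filter imputation of gaps < 5 min, longest
   contiguous-window search (≥ 128 min), and the per-period eligibility
   ladder (outcome/covariates available, ≥ 30 % valid readings in both
   sources, a qualifying contiguous window).
3. **Variability features** (`bpvar.features`, `bpvar.wavelets`) — per
   window (three 8-h periods + full 24 h), per source, per channel:
   mean / max / range / SD / CV / % above threshold (185/110/130 mmHg), and
   five dyadic wavelet-band normalised energies (mmHg²/min) from an
   orthogonal Daubechies DWT with periodized boundaries (implemented
   in-repo; exact energy conservation).
4. **Synthetic cohorts** (`bpvar.simulate`) — band-limited oscillations
   with known analytic energies, artefact spikes, wear-off missingness,
   cuff noise, Table-1-like covariates, and a logistic outcome mechanism on
   latent sub-32-min variability (per-patient seed substreams).
5. **Inference** (`bpvar.inference`, `bpvar.metrics`) — univariable and
   covariate-adjusted logistic ORs per 1-SD feature shift (IRLS, Wald CIs,
   separation fallback), and a stratified 10-fold cross-validated
   comparison of continuous vs intermittent feature sets (rank AUC,
   step-integrated average precision, paired fold t-tests).
6. **Pipeline & CLI** (`bpvar.pipeline`, `bpvar.cli`) — deterministic
   end-to-end runs with a JSON manifest.

## CLI

```bash
# end-to-end on a synthetic cohort (default config)
bpvar run-all --seed 1 --outdir out/

# or from a YAML config / individual stages
bpvar run-all --config config.yaml --seed 1 --outdir out/ --windows P1
bpvar simulate --seed 1 --n-patients 200 --outdir data/
bpvar qc --recordings data/recordings.csv --clinical data/clinical.csv --out elig.csv
bpvar features --recordings data/recordings.csv --clinical data/clinical.csv \
    --window P1 --band-convention finest-2-4min --out features_P1.csv
bpvar associate --features features_P1.csv --clinical data/clinical.csv --out or.csv
bpvar predict --features features_P1.csv --clinical data/clinical.csv --out cv.csv
```

`run-all` writes `recordings.csv`, `clinical.csv`, `ground_truth.csv`,
`eligibility.csv`, `features_<window>.csv`, `odds_ratios_<window>.csv`,
`cv_compare.csv`, `manifest.json` and `summary.txt`; re-running with the
same config and seed reproduces every file bit-identically.

The five band-energy columns are labelled by oscillation-period range. The
default convention (`finest-2-4min`) maps detail level *j* to its physical
period range 2^j–2^(j+1) min on the 1-min grid (so the finest band is
2–4 min and the deepest 32–64 min); `--band-convention finest-1-2min`
shifts the ladder one octave so the labels run 1–2 … 16–32 min.

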