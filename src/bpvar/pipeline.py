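"""End-to-end orchestration: simulate/load -> QC -> features -> association
-> prediction, with deterministic seeding and a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .features import WaveletConfig, build_feature_table
from .inference import crossval_compare, cv_frame, run_association_scan
from .model import WINDOWS, load_cohort, write_table
from .qc import QCConfig, assess_eligibility, eligibility_frame, preprocess_record
from .simulate import SimParams, simulate_cohort, write_cohort_csv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimParams | None = None
    recordings_path: str | None = None
    clinical_path: str | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    windows: tuple = ("P1", "P2", "P3", "FULL24")
    cv_window: str = "P1"
    k_folds: int = 10
    seed: int = 0
    ridge: float = 1.0
    outdir: str = "bpvar_run"

    def __post_init__(self) -> None:
        if self.sim is None and (self.recordings_path is None or self.clinical_path is None):
            raise ValueError("either sim params or input paths must be provided")
        for w in self.windows:
            if w not in WINDOWS:
                raise ValueError(f"unknown window {w!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            for key in ("band_amp_mmhg", "ht_amp_ratio", "nihss_probs"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["sim"] = SimParams(**sim)
        if "qc" in raw:
            raw["qc"] = QCConfig(**raw["qc"])
        if "wavelet" in raw:
            raw["wavelet"] = WaveletConfig(**raw["wavelet"])
        if "windows" in raw:
            raw["windows"] = tuple(raw["windows"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunReport:
    outdir: str
    manifest: dict
    eligible_n: dict  # window -> n
    ht_n: dict  # window -> n
    outputs: list


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write all artefacts under ``config.outdir``.

    Re-running with an identical config reproduces every output
    bit-identically.  On failure, the stage name is reported and partial
    outputs are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "setup"
    try:
        stage = "input"
        if config.sim is not None:
            sim = SimParams(**{**asdict(config.sim), "seed": config.seed})
            records, truth = simulate_cohort(sim)
            write_cohort_csv(records, out / "recordings.csv", out / "clinical.csv")
            truth.to_csv(out / "ground_truth.csv")
            outputs += ["recordings.csv", "clinical.csv", "ground_truth.csv"]
            records, report = load_cohort(out / "recordings.csv", out / "clinical.csv")
        else:
            records, report = load_cohort(config.recordings_path, config.clinical_path)
        if not records:
            raise ValueError("cohort is empty")
        logger.info("%s", report)

        stage = "qc"
        clean = {}
        for pid, rec in records.items():
            clean[pid], _ = preprocess_record(rec, config.qc)

        stage = "eligibility"
        reports = []
        eligible: dict[str, dict] = {}
        for wlabel in config.windows:
            window = WINDOWS[wlabel]
            eligible[wlabel] = {}
            for pid, rec in clean.items():
                rep = assess_eligibility(rec, window, config.qc)
                reports.append(rep)
                if rep.eligible:
                    eligible[wlabel][pid] = rec
        write_table(eligibility_frame(reports), out / "eligibility.csv")
        outputs.append("eligibility.csv")
        if all(len(v) == 0 for v in eligible.values()):
            raise ValueError("no eligible patients in any window")

        stage = "features"
        feature_tables: dict[str, pd.DataFrame] = {}
        for wlabel in config.windows:
            if not eligible[wlabel]:
                logger.warning("window %s: no eligible patients, skipped", wlabel)
                continue
            ft = build_feature_table(eligible[wlabel], WINDOWS[wlabel], config.qc, config.wavelet)
            feature_tables[wlabel] = ft
            write_table(ft.reset_index(), out / f"features_{wlabel}.csv")
            outputs.append(f"features_{wlabel}.csv")

        stage = "association"
        eligible_n = {}
        ht_n = {}
        for wlabel, ft in feature_tables.items():
            recs = eligible[wlabel]
            outcome = pd.Series(
                {pid: int(recs[pid].ht_outcome) for pid in ft.index}, name="ht_outcome"
            )
            cov = pd.DataFrame(
                {
                    pid: {
                        "nihss_category": recs[pid].covariates.nihss_category,
                        "admission_mbp": recs[pid].covariates.admission_mbp,
                        "time_to_reperfusion_h": recs[pid].covariates.time_to_reperfusion_h,
                        "iv_thrombolysis": int(recs[pid].covariates.iv_thrombolysis),
                        "periprocedural_antithrombotic": int(
                            recs[pid].covariates.periprocedural_antithrombotic
                        ),
                    }
                    for pid in ft.index
                }
            ).T
            eligible_n[wlabel] = int(len(ft))
            ht_n[wlabel] = int(outcome.sum())
            scan = run_association_scan(ft, outcome, cov, wlabel)
            if not scan.empty:
                write_table(scan, out / f"odds_ratios_{wlabel}.csv")
                outputs.append(f"odds_ratios_{wlabel}.csv")

        stage = "prediction"
        if config.cv_window in feature_tables:
            ft = feature_tables[config.cv_window]
            recs = eligible[config.cv_window]
            outcome = pd.Series({pid: int(recs[pid].ht_outcome) for pid in ft.index})
            cont = ft[[c for c in ft.columns if c.startswith("cont_")]]
            inter = ft[[c for c in ft.columns if c.startswith("int_")]]
            cvc, cvi, comp = crossval_compare(
                cont, inter, outcome, k=config.k_folds, seed=config.seed,
                ridge=config.ridge, window_label=config.cv_window,
            )
            write_table(cv_frame(cvc, cvi, comp), out / "cv_compare.csv")
            outputs.append("cv_compare.csv")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "windows": list(config.windows),
            "band_convention": config.wavelet.band_convention,
            "eligible_n": eligible_n,
            "ht_n": ht_n,
            "outputs": sorted(outputs),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        report = RunReport(
            outdir=str(out), manifest=manifest, eligible_n=eligible_n, ht_n=ht_n,
            outputs=sorted(outputs) + ["manifest.json"],
        )
        (out / "summary.txt").write_text(summarize_run(report, feature_tables_dir=out))
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def summarize_run(report: RunReport, feature_tables_dir=None) -> str:
    """Human-readable run summary: per-window counts, top associations and
    the prediction comparison."""
    out = Path(report.outdir if feature_tables_dir is None else feature_tables_dir)
    lines = [f"bpvar run ({report.manifest['config_hash'][:12]}), seed {report.manifest['seed']}"]
    for wlabel in report.manifest["windows"]:
        if wlabel not in report.eligible_n:
            lines.append(f"[{wlabel}] no eligible patients")
            continue
        n = report.eligible_n[wlabel]
        ht = report.ht_n[wlabel]
        lines.append(f"[{wlabel}] eligible n={n}, HT n={ht} ({100.0 * ht / n:.0f}%)")
        or_path = out / f"odds_ratios_{wlabel}.csv"
        if or_path.exists():
            scan = pd.read_csv(or_path)
            mv = scan[scan["model"] == "multivariable"].nsmallest(3, "p_value")
            sig = scan[(scan["model"] == "multivariable") & (scan["p_value"] < 0.05)]
            if sig.empty:
                lines.append("  no features significant at alpha=0.05 (multivariable)")
            for _, r in mv.iterrows():
                lines.append(
                    f"  {r['feature']}: OR/SD {r['odds_ratio_per_sd']:.2f} "
                    f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}], p={r['p_value']:.3g}"
                )
    cv_path = out / "cv_compare.csv"
    if cv_path.exists():
        cv = pd.read_csv(cv_path)
        for _, r in cv.iterrows():
            lines.append(
                f"  CV {r['source']}: AUC {r['auc']:.3f} "
                f"[{r['auc_ci_low']:.3f}, {r['auc_ci_high']:.3f}], "
                f"AP {r['ap']:.3f} [{r['ap_ci_low']:.3f}, {r['ap_ci_high']:.3f}]"
            )
        lines.append(
            f"  paired t-tests: AUC p={cv['p_auc'].iloc[0]:.3g}, AP p={cv['p_ap'].iloc[0]:.3g}"
        )
    return "\n".join(lines) + "\n"
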