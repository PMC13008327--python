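"""Association (odds ratios per 1 SD) and cross-validated prediction.

Logistic fits use iteratively reweighted least squares with optional ridge
penalty (never on the intercept) and Wald standard errors from the observed
information.  The association scan reports one univariable and one
covariate-adjusted odds ratio per feature; the prediction comparison trains
ridge-logistic models on all features of each source under a shared
stratified k-fold split and compares fold-wise AUC-ROC / average precision
with paired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, t as t_dist, ttest_rel

from .metrics import auc_rank, average_precision, stratified_folds

ADJUSTMENT_COVARIATES = [
    "nihss_category",
    "admission_mbp",
    "time_to_reperfusion_h",
    "iv_thrombolysis",
    "periprocedural_antithrombotic",
]

#: |coefficient| beyond which an unpenalised fit is treated as separating.
SEPARATION_COEF = 20.0


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _irls(X, y, penalty, max_iter, tol):
    n, p = X.shape
    beta = np.zeros(p)
    A = None
    diverged = False
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = X.T @ (X * w[:, None]) + np.diag(penalty)
        new = np.linalg.solve(A, X.T @ (w * z))
        delta = float(np.max(np.abs(new - beta)))
        beta = new
        if delta < tol:
            return beta, A, True, it, False
        if np.max(np.abs(beta)) > SEPARATION_COEF and not penalty.any():
            diverged = True
            break
    return beta, A, False, it, diverged


def fit_logistic(
    X,
    y,
    ridge: float = 0.0,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    separation_ridge: float = 1.0,
) -> LogisticFit:
    """Maximum-likelihood (or ridge-penalised) logistic regression via IRLS.

    The intercept is never penalised.  If an unpenalised fit diverges
    (coefficients exceeding a separation bound, or non-convergence), the fit
    is flagged and redone with ``separation_ridge``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    if ridge == 0.0:
        sds = X.std(axis=0)
        nonintercept = np.arange(p) > 0 if add_intercept else np.ones(p, bool)
        if np.any((sds == 0) & nonintercept):
            raise ValueError("design contains a zero-variance column")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")

    penalty = np.full(p, ridge)
    if add_intercept:
        penalty[0] = 0.0
    beta, A, converged, it, diverged = _irls(X, y, penalty, max_iter, tol)
    separation = False
    if (diverged or not converged) and ridge == 0.0:
        separation = True
        warnings.warn(
            "logistic fit did not converge (possible separation); "
            f"refitting with ridge={separation_ridge}",
            stacklevel=2,
        )
        penalty = np.full(p, separation_ridge)
        if add_intercept:
            penalty[0] = 0.0
        beta, A, converged, it, _ = _irls(X, y, penalty, max_iter, tol)
    if not converged:
        raise RuntimeError("logistic fit failed to converge")
    return LogisticFit(coef=beta, cov=np.linalg.inv(A), converged=converged, n_iter=it, separation=separation)


@dataclass
class ORResult:
    feature: str
    window: str
    source: str
    model: str  # univariable | multivariable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    separation: bool = False


def adjustment_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Five-covariate adjustment block: NIHSS category as 3 indicator
    contrasts (reference = lowest bin) plus the four remaining covariates."""
    nihss = covariates["nihss_category"].to_numpy(dtype=float)
    dummies = np.column_stack([(nihss == lvl).astype(float) for lvl in (1, 2, 3)])
    rest = covariates[ADJUSTMENT_COVARIATES[1:]].to_numpy(dtype=float)
    return np.column_stack([dummies, rest])


def or_per_sd(
    features: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    feature: str,
    adjusted: bool,
    window_label: str = "",
):
    """Odds ratio for a 1-SD shift of one feature, with 95% Wald CI.

    The feature is standardized by the analysis-set SD; complete cases only.
    Returns ``None`` for degenerate (near-constant) features.
    """
    f = features[feature]
    mask = f.notna() & outcome.notna()
    if adjusted:
        mask &= covariates[ADJUSTMENT_COVARIATES].notna().all(axis=1)
    x = f[mask].to_numpy(dtype=float)
    y = outcome[mask].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        return None
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    z = (x - x.mean()) / sd
    X = z[:, None]
    if adjusted:
        adj = adjustment_matrix(covariates[mask])
        adj = adj[:, adj.std(axis=0) > 0]  # drop empty indicator levels
        X = np.column_stack([X, adj])
    fit = fit_logistic(X, y)
    b = fit.coef[1]
    se = fit.se[1]
    source = "continuous" if feature.startswith("cont_") else "intermittent"
    with np.errstate(over="ignore"):  # degenerate fits may give CI bounds of inf
        or_, lo, hi = np.exp([b, b - 1.96 * se, b + 1.96 * se])
    return ORResult(
        feature=feature,
        window=window_label,
        source=source,
        model="multivariable" if adjusted else "univariable",
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(2.0 * norm.sf(abs(b / se))),
        n=int(mask.sum()),
        separation=fit.separation,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (reported alongside, not used for the
    primary flagging)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def run_association_scan(
    features: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    window_label: str,
) -> pd.DataFrame:
    """Univariable and covariate-adjusted OR per 1 SD for every feature."""
    results: list[ORResult] = []
    for feat in features.columns:
        for adjusted in (False, True):
            r = or_per_sd(features, outcome, covariates, feat, adjusted, window_label)
            if r is not None:
                results.append(r)
    if not results:
        return pd.DataFrame(
            columns=[
                "feature", "window", "source", "model", "odds_ratio_per_sd",
                "ci_low", "ci_high", "p_value", "p_bh", "n", "separation",
            ]
        )
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "window": [r.window for r in results],
            "source": [r.source for r in results],
            "model": [r.model for r in results],
            "odds_ratio_per_sd": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "separation": [r.separation for r in results],
        }
    )
    df["p_bh"] = np.nan
    for model in df["model"].unique():
        m = df["model"] == model
        df.loc[m, "p_bh"] = benjamini_hochberg(df.loc[m, "p_value"].to_numpy())
    cols = [
        "feature", "window", "source", "model", "odds_ratio_per_sd",
        "ci_low", "ci_high", "p_value", "p_bh", "n", "separation",
    ]
    return df[cols]


@dataclass
class CVResult:
    source: str
    window: str
    fold_auc: np.ndarray
    fold_ap: np.ndarray
    seed: int
    k: int

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def ap(self) -> float:
        return float(np.mean(self.fold_ap))

    def _ci(self, vals: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
        half = float(t_dist.ppf(0.975, vals.size - 1)) * se
        return (m - half, m + half)

    @property
    def auc_ci(self) -> tuple[float, float]:
        return self._ci(self.fold_auc)

    @property
    def ap_ci(self) -> tuple[float, float]:
        return self._ci(self.fold_ap)


def _fold_scores(X: np.ndarray, y: np.ndarray, train, test, ridge: float) -> np.ndarray:
    """Train-fold standardization + mean imputation, ridge-logistic score."""
    Xtr = X[train].copy()
    Xte = X[test].copy()
    mean = np.nanmean(Xtr, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    for M in (Xtr, Xte):
        nan = np.isnan(M)
        M[nan] = np.take(mean, np.nonzero(nan)[1])
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    fit = fit_logistic(Xtr, y[train], ridge=ridge)
    return np.column_stack([np.ones(Xte.shape[0]), Xte]) @ fit.coef


def crossval_compare(
    features_continuous: pd.DataFrame,
    features_intermittent: pd.DataFrame,
    outcome: pd.Series,
    k: int = 10,
    seed: int = 0,
    ridge: float = 1.0,
    window_label: str = "P1",
):
    """Stratified k-fold comparison of the two feature sources.

    Both sources use the identical fold assignment (derived from the labels
    and seed only).  Returns ``(cv_continuous, cv_intermittent, comparison)``
    where *comparison* holds the paired two-sided t-tests on the fold-wise
    AUC and AP differences.
    """
    if not features_continuous.index.equals(features_intermittent.index):
        raise ValueError("both sources must cover the same patients in the same order")
    y = outcome.loc[features_continuous.index].to_numpy(dtype=int)
    folds = stratified_folds(y, k, seed)
    all_idx = np.arange(y.size)
    results = {}
    for name, df in (
        ("continuous", features_continuous),
        ("intermittent", features_intermittent),
    ):
        X = df.to_numpy(dtype=float)
        aucs, aps = [], []
        for test in folds:
            train = np.setdiff1d(all_idx, test)
            s = _fold_scores(X, y, train, test, ridge)
            aucs.append(auc_rank(y[test], s))
            aps.append(average_precision(y[test], s))
        results[name] = CVResult(
            source=name, window=window_label,
            fold_auc=np.array(aucs), fold_ap=np.array(aps), seed=seed, k=k,
        )
    d_auc = results["continuous"].fold_auc - results["intermittent"].fold_auc
    d_ap = results["continuous"].fold_ap - results["intermittent"].fold_ap
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance differences -> nan p
        t_auc = ttest_rel(results["continuous"].fold_auc, results["intermittent"].fold_auc)
        t_ap = ttest_rel(results["continuous"].fold_ap, results["intermittent"].fold_ap)
    comparison = {
        "delta_auc": float(np.mean(d_auc)),
        "t_auc": float(t_auc.statistic),
        "p_auc": float(t_auc.pvalue),
        "delta_ap": float(np.mean(d_ap)),
        "t_ap": float(t_ap.statistic),
        "p_ap": float(t_ap.pvalue),
    }
    return results["continuous"], results["intermittent"], comparison


def cv_frame(cv_cont: CVResult, cv_int: CVResult, comparison: dict) -> pd.DataFrame:
    """Tidy summary of a cross-validated comparison."""
    rows = []
    for cv in (cv_cont, cv_int):
        rows.append(
            {
                "source": cv.source,
                "window": cv.window,
                "k": cv.k,
                "seed": cv.seed,
                "auc": cv.auc,
                "auc_ci_low": cv.auc_ci[0],
                "auc_ci_high": cv.auc_ci[1],
                "ap": cv.ap,
                "ap_ci_low": cv.ap_ci[0],
                "ap_ci_high": cv.ap_ci[1],
                **{f"fold{i+1}_auc": v for i, v in enumerate(cv.fold_auc)},
                **{f"fold{i+1}_ap": v for i, v in enumerate(cv.fold_ap)},
            }
        )
    df = pd.DataFrame(rows)
    for key, val in comparison.items():
        df[key] = val
    return df
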