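"""Calibration checks, predictive metrics and a spatial cross-validation harness.

Calibration uses per-margin quantile residuals: with Gaussian conditional
margins, r = Phi^-1(F_m(y_m)) reduces to the standardized residual
(y_m - mu_m) / sd_m, standard normal under a correctly specified model.
Predictive performance is the mean held-out joint log-density, reported
against the intercept-only baseline.  Cross-validation folds reuse the
spatially spread cluster partition from the splitting module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import RESPONSES
from .fitting import FitResult, fit_baseline
from .splitting import spatial_folds

#: two-sided 90% predictive interval half-width in SD units
_Z90 = float(stats.norm.ppf(0.95))


@dataclass
class ValidationReport:
    """Calibration and predictive-performance summary on one test set."""

    residual_summary: pd.DataFrame
    coverage90: dict[str, float]
    logscore: float
    baseline_logscore: float | None = None
    n_excluded: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def logscore_gain(self) -> float | None:
        if self.baseline_logscore is None:
            return None
        return self.logscore - self.baseline_logscore


def quantile_residuals(fit: FitResult, test: pd.DataFrame) -> pd.DataFrame:
    """Per-response quantile residuals on ``test`` under the fitted margins.

    Rows with non-finite fitted scale are flagged (``excluded`` column) and
    left out of the residual values.
    """
    y = test[list(RESPONSES)].to_numpy(dtype=float)
    params = fit.predict_mvn(test)
    ok = np.isfinite(params.sd).all(axis=1) & (params.sd > 0).all(axis=1)
    res = np.full_like(y, np.nan)
    res[ok] = (y[ok] - params.mu[ok]) / params.sd[ok]
    out = pd.DataFrame(res, columns=[f"resid_{r}" for r in RESPONSES], index=test.index)
    out["excluded"] = ~ok
    return out


def _residual_summary(res: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in RESPONSES:
        v = res[f"resid_{r}"].dropna().to_numpy()
        rows.append(
            {
                "response": r,
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "skew": stats.skew(v),
                "excess_kurtosis": stats.kurtosis(v),
            }
        )
    return pd.DataFrame(rows)


def heldout_logscore(fit: FitResult, test: pd.DataFrame) -> float:
    """Mean joint log-density of the test rows; invariant to row order."""
    return fit.mean_loglik(test)


def validate(fit: FitResult, test: pd.DataFrame, baseline: FitResult | None = None) -> ValidationReport:
    """Full calibration report: residual moments, 90% coverage, log-scores."""
    res = quantile_residuals(fit, test)
    keep = ~res["excluded"]
    coverage = {
        r: float((res.loc[keep, f"resid_{r}"].abs() <= _Z90).mean()) for r in RESPONSES
    }
    return ValidationReport(
        residual_summary=_residual_summary(res),
        coverage90=coverage,
        logscore=heldout_logscore(fit, test),
        baseline_logscore=None if baseline is None else heldout_logscore(baseline, test),
        n_excluded=int(res["excluded"].sum()),
    )


def spatial_cv(
    survey: pd.DataFrame,
    spec=None,
    k_folds: int = 5,
    seed: int = 0,
    fit_fn=None,
) -> list[ValidationReport]:
    """Cluster-level spatially spread k-fold cross-validation.

    Each fold holds out one spatially spread set of clusters; the model is
    refitted on the rest with ``fit_fn`` (default: the intercept-only
    baseline; pass e.g. ``lambda tr: fit_mcmc(tr, spec, ...)`` for the full
    model) and validated on the fold.  Fold assignment is an exact partition
    of clusters and reproducible under the seed.
    """
    folds = spatial_folds(survey, k_folds, seed=seed)
    if fit_fn is None:
        def fit_fn(tr, _spec=spec):
            return fit_baseline(tr)

    reports = []
    for fold_clusters in folds:
        in_fold = survey["cluster_id"].isin(fold_clusters)
        train, test = survey[~in_fold], survey[in_fold]
        fit = fit_fn(train)
        rep = validate(fit, test, baseline=fit_baseline(train))
        rep.extras["n_test"] = len(test)
        reports.append(rep)
    return reports


def cv_summary(reports: list[ValidationReport]) -> dict:
    """Mean and SD of held-out log-scores across folds."""
    scores = np.array([r.logscore for r in reports])
    return {
        "mean_logscore": float(scores.mean()),
        "sd_logscore": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        "per_fold": scores.tolist(),
    }
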