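"""Regression models linking ultrasound image statistics to lung aeration.

The response is the CT-measured proportion of air in the superficial 1 cm of
lung, on a percent scale (0-100).  Only observations with a type-1 or type-2
ultrasound appearance enter the models (the 0/0.5/3 types pin the air
fraction tightly on their own).  The stages are:

* simple OLS of air% on one statistic, optionally stratified by inflation /
  deflation phase, with the 95% prediction-interval half-width at the
  covariate mean, ``t(0.975, n-p) * s * sqrt(1 + 1/n)``;
* base-10 log-linearization for the parallel-axis spectral AUC, whose raw
  relationship with air content is logarithmic;
* a multivariate OLS over all statistics plus the ordinal grade (numeric,
  0.5 steps), reduced by stepwise backward elimination at alpha = 0.05;
* group tests: Kruskal-Wallis across grades, paired t-test for the volume
  loss at grade backsliding during deflation.

Fits are ordinary pooled least squares (repeated lungs within lambs are not
modeled as random effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DomainError, SingularDesignError, UndefinedStatisticError

#: Covariates of the full multivariate model, in design order.  The
#: parallel-axis spectral AUC enters on the log10 scale.
MULTIVARIATE_COVARIATES = ("mpi", "cov", "auc_parallel_log", "auc_perpendicular", "grade")


@dataclass
class RegressionFit:
    """OLS fit summary with enough state to predict with intervals."""

    covariates: tuple[str, ...]
    intercept: float
    slopes: dict[str, float]
    r_squared: float
    coefficient_p_values: dict[str, float]
    coefficient_ci95: dict[str, tuple[float, float]]
    residual_sd: float
    n: int
    pi95_halfwidth_at_mean: float
    pi95_halfwidth_mean_over_train: float
    intercept_only: bool = False
    _results: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "intercept": self.intercept,
            "slopes": self.slopes,
            "r_squared": self.r_squared,
            "coefficient_p_values": self.coefficient_p_values,
            "coefficient_ci95": {k: list(v) for k, v in self.coefficient_ci95.items()},
            "residual_sd": self.residual_sd,
            "n": self.n,
            "pi95_halfwidth_at_mean": self.pi95_halfwidth_at_mean,
            "pi95_halfwidth_mean_over_train": self.pi95_halfwidth_mean_over_train,
            "intercept_only": self.intercept_only,
        }


@dataclass(frozen=True)
class EliminationTrace:
    """Backward-elimination history: (covariate, p-value at removal)."""

    removed: tuple[tuple[str, float], ...]
    final_covariates: tuple[str, ...]


@dataclass(frozen=True)
class PredictionResult:
    """Point estimate and 95% prediction interval, percent-air scale."""

    point_estimate: float
    pi95_low: float
    pi95_high: float

    def __post_init__(self) -> None:
        if not self.pi95_low <= self.point_estimate <= self.pi95_high:
            raise DomainError("prediction interval must bracket the point estimate")

    def clamped(self) -> tuple[float, float, float]:
        """Display values with interval bounds clamped to [0, 100] percent."""
        return (
            float(np.clip(self.point_estimate, 0.0, 100.0)),
            float(np.clip(self.pi95_low, 0.0, 100.0)),
            float(np.clip(self.pi95_high, 0.0, 100.0)),
        )


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    group_summaries: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise DomainError("p-value must lie in [0, 1]")


def _fit_ols(X: pd.DataFrame, y: np.ndarray) -> RegressionFit:
    names = tuple(X.columns)
    design = sm.add_constant(X.to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(
            f"design with covariates {names} is rank deficient (constant covariate?)"
        )
    n = len(y)
    if n <= design.shape[1]:
        raise DomainError(f"n = {n} too small for {design.shape[1]} coefficients")
    res = sm.OLS(y, design).fit()
    s = float(np.sqrt(res.mse_resid))
    tcrit = scipy.stats.t.ppf(0.975, res.df_resid)
    half_at_mean = float(tcrit * s * np.sqrt(1 + 1 / n))
    # mean PI half-width over the training points (leverage varies per point)
    hat = (design * np.linalg.solve(design.T @ design, design.T).T).sum(axis=1)
    half_train = float(np.mean(tcrit * s * np.sqrt(1 + hat)))
    ci = res.conf_int(alpha=0.05)
    ci95 = {"intercept": (float(ci[0][0]), float(ci[0][1]))}
    ci95.update(
        {name: (float(lo), float(hi)) for name, (lo, hi) in zip(names, ci[1:])}
    )
    return RegressionFit(
        covariates=names,
        intercept=float(res.params[0]),
        slopes={name: float(b) for name, b in zip(names, res.params[1:])},
        r_squared=float(res.rsquared) if names else 0.0,
        coefficient_p_values={name: float(p) for name, p in zip(names, res.pvalues[1:])},
        coefficient_ci95=ci95,
        residual_sd=s,
        n=n,
        pi95_halfwidth_at_mean=half_at_mean,
        pi95_halfwidth_mean_over_train=half_train,
        _results=res,
    )


def fit_simple_regression(
    x: Sequence[float], y: Sequence[float], covariate_name: str = "x"
) -> RegressionFit:
    """OLS of percent air on a single covariate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise SingularDesignError("covariate is constant")
    return _fit_ols(pd.DataFrame({covariate_name: x}), y)


def log_linearize(values: Sequence[float]) -> np.ndarray:
    """Elementwise base-10 logarithm; rejects non-positive input."""
    values = np.asarray(values, float)
    if np.any(values <= 0):
        raise DomainError("log-linearization requires strictly positive values")
    return np.log10(values)


def fit_multivariate(
    features: pd.DataFrame,
    y: Sequence[float],
    alpha: float = 0.05,
    covariates: Sequence[str] = MULTIVARIATE_COVARIATES,
) -> tuple[RegressionFit, EliminationTrace]:
    """Full model with stepwise backward elimination.

    Repeatedly removes the covariate with the largest p-value while that
    p-value exceeds ``alpha``, refitting after each removal.  If every
    covariate is eliminated the intercept-only fit is returned with
    ``intercept_only=True``.
    """
    y = np.asarray(y, float)
    missing = [c for c in covariates if c not in features.columns]
    if missing:
        raise DomainError(f"features table lacks columns {missing}")
    current = list(covariates)
    if len(y) <= len(current) + 2:
        raise DomainError("n must exceed covariate count + 2")
    removed: list[tuple[str, float]] = []
    while current:
        fit = _fit_ols(features[current], y)
        pvals = fit.coefficient_p_values
        worst = max(current, key=lambda c: pvals[c])
        if pvals[worst] <= alpha:
            return fit, EliminationTrace(tuple(removed), tuple(current))
        removed.append((worst, pvals[worst]))
        current.remove(worst)
    # all covariates eliminated: intercept-only fit with warning status
    mean = float(y.mean())
    s = float(y.std(ddof=1))
    n = len(y)
    tcrit = scipy.stats.t.ppf(0.975, n - 1)
    half = float(tcrit * s * np.sqrt(1 + 1 / n))
    half_ci = tcrit * s / np.sqrt(n)
    fit = RegressionFit(
        covariates=(),
        intercept=mean,
        slopes={},
        r_squared=0.0,
        coefficient_p_values={},
        coefficient_ci95={"intercept": (mean - half_ci, mean + half_ci)},
        residual_sd=s,
        n=n,
        pi95_halfwidth_at_mean=half,
        pi95_halfwidth_mean_over_train=half,
        intercept_only=True,
    )
    return fit, EliminationTrace(tuple(removed), ())


def predict_air_proportion(fit: RegressionFit, features: Mapping[str, float]) -> PredictionResult:
    """Point estimate with the full OLS 95% prediction interval (leverage
    term included) at the supplied covariate point."""
    missing = [c for c in fit.covariates if c not in features]
    if missing:
        raise DomainError(f"prediction point lacks covariates {missing}")
    if fit.intercept_only or fit._results is None:
        point = fit.intercept
        return PredictionResult(
            point_estimate=point,
            pi95_low=point - fit.pi95_halfwidth_at_mean,
            pi95_high=point + fit.pi95_halfwidth_at_mean,
        )
    row = np.r_[1.0, [features[c] for c in fit.covariates]].reshape(1, -1)
    pred = fit._results.get_prediction(row)
    frame = pred.summary_frame(alpha=0.05)
    return PredictionResult(
        point_estimate=float(frame["mean"].iloc[0]),
        pi95_low=float(frame["obs_ci_lower"].iloc[0]),
        pi95_high=float(frame["obs_ci_upper"].iloc[0]),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H on mid-ranks with tie correction; chi-square p with
    k-1 degrees of freedom."""
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise DomainError("all groups must be non-empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        # every value identical: all mid-ranks tie, H = 0 by definition
        stat, p = 0.0, 1.0
    else:
        stat, p = scipy.stats.kruskal(*arrays)
    summaries = tuple(
        {
            "n": len(g),
            "median": float(np.median(g)),
            "iqr_low": float(np.quantile(g, 0.25)),
            "iqr_high": float(np.quantile(g, 0.75)),
        }
        for g in arrays
    )
    return GroupComparison(statistic=float(stat), p_value=float(p), group_summaries=summaries)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided paired t-test on the differences a - b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("paired samples must be 1-D arrays of equal length")
    if len(a) < 2:
        raise DomainError("need at least 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0:
        raise UndefinedStatisticError("paired t undefined for zero-variance differences")
    stat, p = scipy.stats.ttest_rel(a, b)
    summaries = (
        {"n": len(a), "mean": float(a.mean())},
        {"n": len(b), "mean": float(b.mean())},
        {"mean_difference": float(d.mean()), "sd_difference": float(d.std(ddof=1))},
    )
    return GroupComparison(statistic=float(stat), p_value=float(p), group_summaries=summaries)
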