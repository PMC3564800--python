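"""Per-cohort covariate-adjusted associations on the percent scale.

All outcome phenotypes are natural-log transformed before regression, so a
coefficient multiplied by 100 is a percent difference in the raw trait per
unit of exposure.  Month of blood draw enters as a categorical variable
(indicator columns) to absorb seasonal variation; any other non-numeric
covariate is likewise expanded to indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .errors import ConfigurationError, SingularDesignError, UndefinedR2Error

_Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AssocEstimate:
    """A (beta, se, n) regression coefficient on the percent scale."""

    beta: float
    se: float
    n: int
    outcome: str = ""
    exposure: str = ""
    covariates: tuple[str, ...] = ()
    cohort: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ConfigurationError("AssocEstimate.se must be > 0")

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se


@dataclass(frozen=True)
class BivariateEstimate:
    """Two jointly-estimated coefficients with their within-study covariance."""

    beta_pair: tuple[float, float]
    cov: np.ndarray  # 2x2, percent^2 scale
    cohort: str = ""
    labels: tuple[str, str] = ("synthesis_score", "metabolism_score")
    n: int = 0

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T, atol=1e-10):
            raise ConfigurationError("BivariateEstimate.cov must be symmetric 2x2")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ConfigurationError("BivariateEstimate.cov must be PSD")
        object.__setattr__(self, "cov", c)


def _ln_outcome(table: pd.DataFrame, outcome: str) -> pd.Series:
    """ln of the outcome column; columns already on the ln scale pass through."""
    y = table[outcome]
    if outcome.startswith("ln_"):
        return y.astype(float)
    if (y <= 0).any():
        raise ConfigurationError(
            f"outcome {outcome!r} must be strictly positive before ln-transform"
        )
    return np.log(y.astype(float))


def _expand_covariates(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariates pass through; categorical ones become indicators.

    A categorical covariate with a single observed level (e.g. a cohort
    sampled in one month) is dropped with a warning rather than erroring.
    """
    cols = []
    for cov in covariates:
        if cov not in table.columns:
            raise ConfigurationError(f"covariate column missing: {cov!r}")
        series = table[cov]
        categorical = (
            cov == "month"
            or series.dtype == object
            or isinstance(series.dtype, pd.CategoricalDtype)
            or series.dtype == bool
        )
        if categorical:
            levels = pd.unique(series.dropna())
            if len(levels) < 2:
                warnings.warn(
                    f"covariate {cov!r} has a single level; dropped",
                    UserWarning,
                    stacklevel=3,
                )
                continue
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True)
            cols.append(dummies.astype(float))
        else:
            cols.append(series.astype(float).to_frame(cov))
    if not cols:
        return pd.DataFrame(index=table.index)
    return pd.concat(cols, axis=1)


def _check_rank(design: pd.DataFrame) -> None:
    """Raise :class:`SingularDesignError` naming dependent columns."""
    x = design.to_numpy(dtype=float)
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        bad = [design.columns[j] for j in piv[rank:]]
        raise SingularDesignError(sorted(map(str, bad)))


def adjusted_percent_association(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates=(),
    cohort: str = "",
) -> AssocEstimate:
    """OLS of ln(outcome) on exposure + covariates; beta and se are x100.

    Rows with a missing value in any used column are excluded; ``n`` is the
    number of rows actually fitted.
    """
    covariates = tuple(covariates)
    y = _ln_outcome(table, outcome)
    x = _expand_covariates(table, covariates)
    x.insert(0, exposure, table[exposure].astype(float))
    frame = pd.concat([y.rename("_y"), x], axis=1).dropna()
    if frame.shape[0] <= frame.shape[1] + 1:
        raise ConfigurationError(
            f"n={frame.shape[0]} does not exceed the number of model parameters"
        )
    design = sm.add_constant(frame.drop(columns="_y"), has_constant="add")
    _check_rank(design)
    fit = sm.OLS(frame["_y"].to_numpy(), design.to_numpy()).fit()
    idx = list(design.columns).index(exposure)
    return AssocEstimate(
        beta=100.0 * float(fit.params[idx]),
        se=100.0 * float(fit.bse[idx]),
        n=int(fit.nobs),
        outcome=outcome,
        exposure=exposure,
        covariates=covariates,
        cohort=cohort,
    )


def joint_percent_association(
    table: pd.DataFrame,
    outcome: str,
    exposures: tuple[str, str],
    covariates=(),
    cohort: str = "",
) -> BivariateEstimate:
    """Joint OLS of ln(outcome) on two exposures; returns betas and 2x2 cov."""
    covariates = tuple(covariates)
    y = _ln_outcome(table, outcome)
    x = _expand_covariates(table, covariates)
    for j, expo in enumerate(exposures):
        x.insert(j, expo, table[expo].astype(float))
    frame = pd.concat([y.rename("_y"), x], axis=1).dropna()
    if frame.shape[0] <= frame.shape[1] + 1:
        raise ConfigurationError(
            f"n={frame.shape[0]} does not exceed the number of model parameters"
        )
    design = sm.add_constant(frame.drop(columns="_y"), has_constant="add")
    _check_rank(design)
    fit = sm.OLS(frame["_y"].to_numpy(), design.to_numpy()).fit()
    cols = list(design.columns)
    idx = [cols.index(e) for e in exposures]
    cov = np.asarray(fit.cov_params())[np.ix_(idx, idx)] * 100.0**2
    return BivariateEstimate(
        beta_pair=(100.0 * float(fit.params[idx[0]]),
                   100.0 * float(fit.params[idx[1]])),
        cov=cov,
        cohort=cohort,
        labels=tuple(exposures),
        n=int(fit.nobs),
    )


def variance_explained(
    table: pd.DataFrame, score, phenotype: str, covariates=None
) -> float:
    """Variance in ln(phenotype) explained by the score.

    By default the marginal R^2 (squared Pearson correlation of score and
    ln-phenotype).  With ``covariates`` the incremental R^2 is returned
    instead: the gain in model R^2 from adding the score to the
    covariate-only regression.
    """
    score = pd.Series(np.asarray(score, dtype=float), index=table.index)
    y = _ln_outcome(table, phenotype)
    if covariates:
        x = _expand_covariates(table, tuple(covariates))
        frame = pd.concat([score.rename("_s"), y.rename("_y"), x], axis=1)
        frame = frame.dropna()
        if frame.shape[0] <= frame.shape[1] + 1:
            raise ConfigurationError("too few rows for incremental R^2")
        if np.var(frame["_s"].to_numpy()) == 0.0:
            raise UndefinedR2Error("score has zero variance; R^2 undefined")
        base = sm.add_constant(
            frame.drop(columns=["_y", "_s"]), has_constant="add"
        )
        full = sm.add_constant(frame.drop(columns="_y"), has_constant="add")
        yv = frame["_y"].to_numpy()
        r2_base = sm.OLS(yv, base.to_numpy()).fit().rsquared
        r2_full = sm.OLS(yv, full.to_numpy()).fit().rsquared
        return float(r2_full - r2_base)
    frame = pd.concat([score.rename("_s"), y.rename("_y")], axis=1).dropna()
    if frame.shape[0] <= 2:
        raise ConfigurationError("variance_explained needs n > 2")
    s = frame["_s"].to_numpy()
    if np.ptp(s) == 0.0 or np.var(s) == 0.0:
        raise UndefinedR2Error("score has zero variance; R^2 undefined")
    r = np.corrcoef(s, frame["_y"].to_numpy())[0, 1]
    return float(r * r)
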