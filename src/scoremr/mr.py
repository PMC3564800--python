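"""Causal inference layer: IV ratios, instrument strength, summary-statistic
score combination, effect-scale conversion, and power by simulation.

The Wald/IV ratio divides the pooled score–outcome association by the pooled
score–exposure association.  Its variance uses the first-order Taylor (delta
method) expansion with zero covariance between numerator and denominator:

    var(r) = se_num^2 / b_den^2 + b_num^2 * se_den^2 / b_den^4

An optional covariance term can be supplied when the two pooled coefficients
come from strongly overlapping samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .associate import AssocEstimate
from .errors import ConfigurationError, UndefinedRatioError
from .meta import fixed_effects

_Z95 = 1.959964


@dataclass(frozen=True)
class IVResult:
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    numerator_ref: str = ""
    denominator_ref: str = ""
    weak_denominator: bool = False

    def __post_init__(self):
        if self.se <= 0:
            raise ConfigurationError("IVResult.se must be > 0")


@dataclass(frozen=True)
class PowerResult:
    effect: float
    n: int
    alpha: float
    reps: int
    power: float
    mc_se: float
    instrument_r2: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.power <= 1.0:
            raise ConfigurationError("power must lie in [0,1]")


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """Standard error back-computed from a 95% normal-theory CI."""
    if ci_high <= ci_low:
        raise ConfigurationError("ci_high must exceed ci_low")
    return (ci_high - ci_low) / (2.0 * _Z95)


def iv_ratio(num, den, covariance: float = 0.0) -> IVResult:
    """Wald ratio num.beta / den.beta with delta-method variance.

    ``num`` and ``den`` are any objects with ``beta`` and ``se`` attributes
    (pooled meta-estimates or single-study associations) on the same percent
    scale.  A denominator with |beta|/se < 2 flags the result as
    weak-denominator rather than switching estimators.
    """
    b_n, s_n = float(num.beta), float(num.se)
    b_d, s_d = float(den.beta), float(den.se)
    if b_d == 0.0:
        raise UndefinedRatioError("denominator association is exactly zero")
    ratio = b_n / b_d
    var = (
        s_n**2 / b_d**2
        + b_n**2 * s_d**2 / b_d**4
        - 2.0 * b_n * covariance / b_d**3
    )
    if var <= 0:
        raise ConfigurationError("non-positive IV variance (check covariance)")
    se = float(np.sqrt(var))
    weak = abs(b_d) / s_d < 2.0
    if weak:
        warnings.warn(
            "weak denominator: |beta|/se < 2 for the instrument-exposure "
            "association; the ratio estimate may be unstable",
            UserWarning,
            stacklevel=2,
        )
    z = ratio / se
    return IVResult(
        ratio=float(ratio),
        se=se,
        ci_low=float(ratio - _Z95 * se),
        ci_high=float(ratio + _Z95 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        numerator_ref=getattr(num, "outcome", "") or "numerator",
        denominator_ref=getattr(den, "outcome", "") or "denominator",
        weak_denominator=weak,
    )


def instrument_f(r2: float, n: int) -> float:
    """Instrument-strength F approximated from variance explained.

    F = (R^2 * (n - 2)) / (1 - R^2); values above ~10 conventionally indicate
    a non-weak instrument.
    """
    if not 0.0 <= r2 < 1.0:
        raise ConfigurationError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ConfigurationError("n must exceed 2")
    return float(r2 * (n - 2) / (1.0 - r2))


def summary_score(per_snp, weights=None) -> AssocEstimate:
    """Combine per-SNP summary associations into an allele-score association.

    Each SNP's (beta, se) is first rescaled to the per-score-unit scale by
    dividing by its predefined weight (unit weights leave unweighted scores
    unchanged), then the rescaled estimates are pooled by inverse-variance
    fixed effects.  Mirrors the approximation used for summary-level
    consortium data where individual genotypes are unavailable.
    """
    per_snp = list(per_snp)
    if not per_snp:
        raise ConfigurationError("summary_score needs at least one SNP")
    if weights is None:
        weights = [1.0] * len(per_snp)
    weights = [float(w) for w in weights]
    if len(weights) != len(per_snp):
        raise ConfigurationError("one weight per SNP required")
    if any(w <= 0 for w in weights):
        raise ConfigurationError("score weights must be > 0")

    scaled = [
        AssocEstimate(
            beta=est.beta / w,
            se=est.se / w,
            n=est.n,
            outcome=est.outcome,
            exposure=est.exposure,
            cohort=est.cohort,
        )
        for est, w in zip(per_snp, weights)
    ]
    if len(scaled) == 1:
        return scaled[0]
    pooled = fixed_effects(scaled)
    return AssocEstimate(
        beta=pooled.beta,
        se=pooled.se,
        n=max(est.n for est in per_snp),
        outcome=per_snp[0].outcome,
        exposure="allele_score",
        cohort=per_snp[0].cohort,
    )


def percent_change_per_10pct(iv: IVResult) -> IVResult:
    """Rescale a percent-per-percent elasticity to per-10%-exposure units.

    Linear x10 scaling of the ratio and its CI (the log-log elasticity is
    locally linear); the p-value is unchanged.
    """
    return IVResult(
        ratio=10.0 * iv.ratio,
        se=10.0 * iv.se,
        ci_low=10.0 * iv.ci_low,
        ci_high=10.0 * iv.ci_high,
        p=iv.p,
        numerator_ref=iv.numerator_ref,
        denominator_ref=iv.denominator_ref + " (per 10% exposure)",
        weak_denominator=iv.weak_denominator,
    )


def _slope_and_se(z: np.ndarray, y: np.ndarray):
    """Per-row OLS slope of y on z with its standard error (vectorised)."""
    n = z.shape[1]
    zc = z - z.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    szz = np.einsum("ij,ij->i", zc, zc)
    szy = np.einsum("ij,ij->i", zc, yc)
    slope = szy / szz
    resid_ss = np.einsum("ij,ij->i", yc, yc) - slope**2 * szz
    se = np.sqrt(resid_ss / (n - 2) / szz)
    return slope, se


def iv_power(
    effect: float,
    n: int,
    instrument_r2: float,
    resid_sd: float = 0.35,
    alpha: float = 0.05,
    reps: int = 2000,
    seed=0,
    chunk: int = 64,
) -> PowerResult:
    """IV-regression power by simulation.

    Per replicate: an instrument score Z ~ N(0,1) explains ``instrument_r2``
    of a standardised ln-exposure X; the exposure is binned into population
    deciles and the ln-outcome mean shifts by ``effect`` log units per decile
    (centred at the mean decile 5.5) on top of N(0, resid_sd^2) noise.  The
    IV ratio (outcome-on-Z over decile-on-Z) is tested at ``alpha``; power is
    the rejection fraction with Monte Carlo binomial standard error.
    """
    if reps < 100:
        raise ConfigurationError("reps must be >= 100")
    if not 0.0 < instrument_r2 < 1.0:
        raise ConfigurationError("instrument_r2 must lie in (0,1)")
    if resid_sd <= 0:
        raise ConfigurationError("resid_sd must be > 0")
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        z = rng.standard_normal((m, n))
        x = np.sqrt(instrument_r2) * z + np.sqrt(1.0 - instrument_r2) * (
            rng.standard_normal((m, n))
        )
        decile = np.clip(np.ceil(10.0 * stats.norm.cdf(x)), 1, 10)
        y = effect * (decile - 5.5) + resid_sd * rng.standard_normal((m, n))
        b_num, se_num = _slope_and_se(z, y)
        b_den, se_den = _slope_and_se(z, decile)
        ratio = b_num / b_den
        var = se_num**2 / b_den**2 + b_num**2 * se_den**2 / b_den**4
        pvals = 2.0 * stats.norm.sf(np.abs(ratio) / np.sqrt(var))
        rejections += int((pvals < alpha).sum())
        done += m
    power = rejections / reps
    return PowerResult(
        effect=effect,
        n=n,
        alpha=alpha,
        reps=reps,
        power=power,
        mc_se=float(np.sqrt(power * (1.0 - power) / reps)),
        instrument_r2=instrument_r2,
    )
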