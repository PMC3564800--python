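"""Meta-analysis engine.

Implements inverse-variance fixed-effects pooling, DerSimonian–Laird
random-effects pooling, Cochran's Q / I^2 heterogeneity diagnostics,
heterogeneity-driven model selection, method-of-moments univariate
meta-regression with a normal approximation for inference, and fixed-effects
multivariate (bivariate) pooling by generalised least squares using the
study-specific within-study covariance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientStudiesError,
    NoContrastError,
)

_Z95 = 1.959964


@dataclass(frozen=True)
class MetaEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    k: int
    Q: float
    p_Q: float
    i2: float
    tau2: float
    model: str  # "fixed" or "random"

    def __post_init__(self):
        if self.se <= 0:
            raise ConfigurationError("MetaEstimate.se must be > 0")
        if self.tau2 < 0 or not 0.0 <= self.i2 <= 100.0:
            raise ConfigurationError("invalid heterogeneity diagnostics")


def _betas_ses(estimates):
    """Accept AssocEstimate-likes (with .beta/.se) or plain (beta, se) pairs."""
    betas, ses = [], []
    for est in estimates:
        if hasattr(est, "beta"):
            betas.append(float(est.beta))
            ses.append(float(est.se))
        else:
            b, s = est
            betas.append(float(b))
            ses.append(float(s))
    b = np.asarray(betas)
    s = np.asarray(ses)
    if len(b) < 2:
        raise InsufficientStudiesError("meta-analysis requires k >= 2 studies")
    if (s <= 0).any():
        raise ConfigurationError("all standard errors must be > 0")
    return b, s


def _q_statistic(b: np.ndarray, s: np.ndarray):
    w = 1.0 / s**2
    b_fixed = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_fixed) ** 2))
    return q, b_fixed, w


def heterogeneity(estimates) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value (k-1 df), and I^2 in percent."""
    b, s = _betas_ses(estimates)
    q, _, _ = _q_statistic(b, s)
    df = len(b) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return q, p_q, i2


def _assemble(beta, se, k, q, p_q, i2, tau2, model) -> MetaEstimate:
    z = beta / se
    return MetaEstimate(
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        k=int(k),
        Q=float(q),
        p_Q=float(p_q),
        i2=float(i2),
        tau2=float(tau2),
        model=model,
    )


def fixed_effects(estimates) -> MetaEstimate:
    """Inverse-variance fixed-effects pooling."""
    b, s = _betas_ses(estimates)
    q, b_fixed, w = _q_statistic(b, s)
    se = float(1.0 / np.sqrt(np.sum(w)))
    df = len(b) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return _assemble(b_fixed, se, len(b), q, p_q, i2, 0.0, "fixed")


def dersimonian_laird(estimates) -> MetaEstimate:
    """Random-effects pooling with the DerSimonian–Laird moment tau^2.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effects
    weights w = 1/se^2; the estimates are then re-weighted by
    1/(se^2 + tau^2).  When Q <= k-1 this reduces exactly to fixed effects.
    """
    b, s = _betas_ses(estimates)
    q, _, w = _q_statistic(b, s)
    k = len(b)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return _assemble(beta, se, k, q, p_q, i2, tau2, "random")


def reml_random_effects(estimates) -> MetaEstimate:
    """Random-effects pooling with the REML tau^2 (alternative to DL).

    Maximises the restricted likelihood of tau^2 numerically; pooling then
    proceeds with weights 1/(se^2 + tau^2) as usual.
    """
    from scipy.optimize import minimize_scalar

    b, s = _betas_ses(estimates)
    v = s**2

    def neg_restricted_loglik(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * b) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (b - mu) ** 2)
        )

    upper = float(np.var(b, ddof=1) * 10 + v.max())
    res = minimize_scalar(
        neg_restricted_loglik, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = max(0.0, float(res.x))
    w_star = 1.0 / (v + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    q, _, _ = _q_statistic(b, s)
    df = len(b) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return _assemble(beta, se, len(b), q, p_q, i2, tau2, "random")


def pool(
    estimates, alpha_het: float = 0.05, tau2_estimator: str = "dl"
) -> MetaEstimate:
    """Heterogeneity-driven model selection: random effects when p_Q < alpha.

    At the boundary p_Q == alpha the fixed-effects model is used (strict
    inequality).  ``tau2_estimator`` selects "dl" (default) or "reml" for the
    random-effects branch.
    """
    if tau2_estimator not in ("dl", "reml"):
        raise ConfigurationError(f"unknown tau2 estimator {tau2_estimator!r}")
    _, p_q, _ = heterogeneity(estimates)
    if p_q < alpha_het:
        if tau2_estimator == "reml":
            return reml_random_effects(estimates)
        return dersimonian_laird(estimates)
    return fixed_effects(estimates)


@dataclass(frozen=True)
class MetaRegressionTerm:
    name: str
    slope: float
    se: float
    p: float


@dataclass(frozen=True)
class MetaRegressionResult:
    terms: tuple[MetaRegressionTerm, ...]
    tau2: float
    q_e: float
    k: int
    reference: str | None = None

    @property
    def p(self) -> float:
        """p-value of the (first) contrast — convenient for single-factor runs."""
        return self.terms[0].p


def meta_regression(
    estimates, study_covariate, reference=None, knapp_hartung: bool = False
) -> MetaRegressionResult:
    """Univariate meta-regression of study effects on a study-level factor.

    Numeric covariates enter linearly; categorical covariates are expanded to
    indicators against ``reference`` (default: first level in sorted order).
    Between-study variance is the method-of-moments estimate from the
    fixed-effects-weighted residual Q_E; inference is a normal approximation
    on the re-weighted WLS fit.  ``study_covariate=None`` fits the
    intercept-only model, which reproduces the DerSimonian–Laird pooled
    estimate.  ``knapp_hartung`` switches to the small-sample variance
    adjustment with t-based inference on k - p degrees of freedom.
    """
    b, s = _betas_ses(estimates)
    k = len(b)
    if study_covariate is None:
        design = np.ones((k, 1))
        names = ["intercept"]
        ref = None
        return _metareg_fit(b, s, design, names, ref, intercept_term=True,
                            knapp_hartung=knapp_hartung)
    cov = np.asarray(study_covariate, dtype=object)
    if cov.shape[0] != k:
        raise ConfigurationError("study_covariate length must match estimates")

    numeric = all(isinstance(v, (int, float, np.integer, np.floating)) for v in cov)
    if numeric:
        x = cov.astype(float)
        if np.ptp(x) == 0.0:
            raise NoContrastError("covariate is constant across studies")
        design = np.column_stack([np.ones(k), x])
        names = ["slope"]
        ref = None
    else:
        levels = sorted({str(v) for v in cov})
        if len(levels) < 2:
            raise NoContrastError("covariate is constant across studies")
        ref = str(reference) if reference is not None else levels[0]
        if ref not in levels:
            raise ConfigurationError(f"reference level {ref!r} not observed")
        contrast_levels = [lv for lv in levels if lv != ref]
        design = np.column_stack(
            [np.ones(k)] + [(cov.astype(str) == lv).astype(float)
                            for lv in contrast_levels]
        )
        names = [f"{lv} vs {ref}" for lv in contrast_levels]
    return _metareg_fit(b, s, design, names, ref,
                        knapp_hartung=knapp_hartung)


def _metareg_fit(b, s, design, names, ref, intercept_term: bool = False,
                 knapp_hartung: bool = False):
    k = len(b)
    p_par = design.shape[1]
    n_contrasts = p_par if intercept_term else p_par - 1
    if k < n_contrasts + 2:
        raise InsufficientStudiesError(
            f"meta-regression with {n_contrasts} contrast(s) needs "
            f"k >= {n_contrasts + 2}"
        )

    # Method-of-moments residual tau^2 from the fixed-weights fit.
    w = 1.0 / s**2
    wx = design * w[:, None]
    xtwx = design.T @ wx
    beta_f = np.linalg.solve(xtwx, wx.T @ b)
    resid = b - design @ beta_f
    q_e = float(np.sum(w * resid**2))
    trace_term = float(np.trace(np.linalg.solve(xtwx, design.T @ (design * (w**2)[:, None]))))
    denom = float(np.sum(w) - trace_term)
    tau2 = max(0.0, (q_e - (k - p_par)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (s**2 + tau2)
    wx = design * w_star[:, None]
    xtwx = np.linalg.inv(design.T @ wx)
    beta = xtwx @ (wx.T @ b)
    se = np.sqrt(np.diag(xtwx))
    if knapp_hartung:
        resid_star = b - design @ beta
        s2 = float(np.sum(w_star * resid_star**2) / (k - p_par))
        se = se * np.sqrt(s2)
    terms = []
    start = 0 if intercept_term else 1
    for j, name in enumerate(names, start=start):
        z = beta[j] / se[j]
        if knapp_hartung:
            p_val = float(2.0 * stats.t.sf(abs(z), df=k - p_par))
        else:
            p_val = float(2.0 * stats.norm.sf(abs(z)))
        terms.append(
            MetaRegressionTerm(
                name=name,
                slope=float(beta[j]),
                se=float(se[j]),
                p=p_val,
            )
        )
    return MetaRegressionResult(
        terms=tuple(terms), tau2=tau2, q_e=q_e, k=k, reference=ref
    )


def multivariate_pool(bivariate, random_effects: bool = False):
    """Fixed-effects GLS pooling of paired coefficients.

    Pooled vector = (sum C_i^-1)^-1 sum(C_i^-1 b_i) with covariance
    (sum C_i^-1)^-1; the joint null is tested by the 2-df Wald quadratic form.
    Studies with a singular within-study covariance are dropped with a
    warning.  With ``random_effects`` a method-of-moments between-study
    covariance (sample covariance of effects minus mean within-study
    covariance, eigenvalue-clipped to PSD) is added to each C_i.

    Returns ``((MetaEstimate, MetaEstimate), joint_p)``.
    """
    usable = []
    for est in bivariate:
        c = np.asarray(est.cov, dtype=float)
        if np.linalg.cond(c) > 1e12 or not np.isfinite(c).all():
            warnings.warn(
                f"dropping study {est.cohort!r}: singular within-study covariance",
                UserWarning,
                stacklevel=2,
            )
            continue
        usable.append((np.asarray(est.beta_pair, dtype=float), c))
    if len(usable) < 2:
        raise InsufficientStudiesError(
            "multivariate pooling requires k >= 2 studies with invertible "
            "covariance matrices"
        )

    if random_effects:
        betas = np.array([b for b, _ in usable])
        mean_within = np.mean([c for _, c in usable], axis=0)
        psi = np.cov(betas.T, ddof=1) - mean_within
        evals, evecs = np.linalg.eigh(psi)
        psi = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        usable = [(b, c + psi) for b, c in usable]

    sum_inv = np.zeros((2, 2))
    sum_invb = np.zeros(2)
    for b, c in usable:
        cinv = np.linalg.inv(c)
        sum_inv += cinv
        sum_invb += cinv @ b
    v = np.linalg.inv(sum_inv)
    beta = v @ sum_invb
    wald = float(beta @ np.linalg.solve(v, beta))
    joint_p = float(stats.chi2.sf(wald, df=2))

    k = len(usable)
    components = tuple(
        _assemble(beta[j], np.sqrt(v[j, j]), k, np.nan, np.nan, 0.0, 0.0,
                  "random" if random_effects else "fixed")
        for j in range(2)
    )
    return components, joint_p
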