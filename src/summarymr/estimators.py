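"""Causal-effect estimators for two-sample Mendelian randomization.

Per-variant Wald ratios are pooled by the inverse-variance weighted (IVW)
family.  Writing beta_x, se_x for the variant-exposure association and
beta_y, se_y for the variant-outcome association (a log odds ratio for a
binary outcome), the Wald ratio for variant j is

    ratio_j = beta_y_j / beta_x_j,    se(ratio_j) = se_y_j / |beta_x_j|

(first-order delta method, treating the exposure association as precisely
estimated).  The IVW estimate is the precision-weighted mean of the ratios
with weights w_j = se(ratio_j)^-2 = beta_x_j^2 / se_y_j^2, algebraically the
slope of the no-intercept weighted regression of beta_y on beta_x with
weights se_y^-2.

Two refinements guard against invalid instruments:

* **Penalized weights** — each variant's heterogeneity contribution
  Q_j = w_j (ratio_j - ivw)^2 is referred to a chi-square(1) distribution; its
  weight is multiplied by min(1, penalty_mult * p_j), sharply downweighting
  outlying ratios while leaving concordant ones untouched.
* **Robust regression** — the pooled fit minimizes a Tukey bisquare loss
  (tuning constant 4.685, 95% Gaussian efficiency) via iteratively reweighted
  least squares with a median-absolute-deviation scale.

MR-Egger regression adds an unconstrained intercept to the weighted
regression of beta_y on beta_x after orienting every variant so beta_x >= 0;
an intercept distinguishable from zero estimates average directional
pleiotropy, and the slope is a pleiotropy-adjusted causal estimate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .summary_io import HarmonizedVariant

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile used for all Wald-type confidence intervals
Z95 = 1.959964

#: Tukey bisquare tuning constant (95% efficiency under Gaussian errors)
TUKEY_C = 4.685

#: default multiplier on the chi-square(1) tail probability in penalized weights
DEFAULT_PENALTY_MULT = 20.0

POOL_METHODS = ("ivw", "ivw_penalized", "ivw_robust", "ivw_penalized_robust")


class EstimationError(ValueError):
    """An estimator's preconditions are not met."""


@dataclass(frozen=True)
class WaldEstimate:
    """Per-variant causal estimate (ratio of outcome to exposure association)."""

    variant_id: str
    beta_xy: float
    se_xy: float

    def __post_init__(self) -> None:
        if not self.se_xy > 0:
            raise EstimationError(f"{self.variant_id}: se_xy must be > 0")

    @property
    def weight(self) -> float:
        """Inverse-variance weight, exactly se_xy ** -2."""
        return self.se_xy ** -2


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled causal effect on the log-OR scale with a 95% CI on the OR scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_variants: int
    variant_ids: tuple[str, ...]
    penalty_factors: np.ndarray = field(repr=False)
    robust_weights: np.ndarray = field(repr=False)
    residual_scale: float = float("nan")
    converged: bool = True

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_variants": self.n_variants,
        }


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger regression: intercept = average directional pleiotropy."""

    intercept: float
    intercept_se: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_p: float
    slope: float
    slope_se: float
    slope_p: float
    residual_scale: float
    n_variants: int
    penalty_factors: np.ndarray = field(repr=False)
    robust_weights: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_ci_low": self.intercept_ci_low,
            "intercept_ci_high": self.intercept_ci_high,
            "intercept_p": self.intercept_p,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_p": self.slope_p,
            "residual_scale": self.residual_scale,
            "n_variants": self.n_variants,
        }


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q against the IVW pooled estimate."""

    q_total: float
    df: int
    pvalue: float
    q_contributions: np.ndarray = field(repr=False)
    variant_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"q_total": self.q_total, "df": self.df, "pvalue": self.pvalue}


@dataclass(frozen=True)
class RobustFit:
    coefficients: np.ndarray
    robust_weights: np.ndarray
    scale: float
    converged: bool
    n_iter: int


def wald_ratio(h: HarmonizedVariant, se_method: str = "delta") -> WaldEstimate:
    """Per-variant causal estimate beta_y / beta_x.

    ``se_method="delta"`` (default) uses the first-order delta method
    se_y / |beta_x|.  ``se_method="literal"`` divides the two standard errors
    (se_y / se_x); this rule is dimensionally inconsistent and provided only
    for auditing analyses that used it.
    """
    if h.beta_exposure == 0:
        raise EstimationError(
            f"{h.variant_id}: exposure beta is zero, Wald ratio undefined")
    if se_method == "delta":
        se = h.se_outcome / abs(h.beta_exposure)
    elif se_method == "literal":
        se = h.se_outcome / h.se_exposure
    else:
        raise ValueError("se_method must be 'delta' or 'literal'")
    return WaldEstimate(
        variant_id=h.variant_id,
        beta_xy=h.beta_outcome / h.beta_exposure,
        se_xy=se,
    )


def wald_ratios(
    variants: Sequence[HarmonizedVariant], se_method: str = "delta"
) -> list[WaldEstimate]:
    return [wald_ratio(h, se_method=se_method) for h in variants]


def penalty_factors(
    estimates: Sequence[WaldEstimate],
    reference_beta: float,
    penalty_mult: float = DEFAULT_PENALTY_MULT,
) -> np.ndarray:
    """Per-variant weight multipliers min(1, penalty_mult * p_j).

    p_j is the upper chi-square(1) tail probability of the variant's
    heterogeneity contribution Q_j = w_j (ratio_j - reference_beta)^2.
    Concordant variants keep factor 1; outliers are downweighted smoothly.
    """
    if not math.isfinite(reference_beta):
        raise EstimationError("reference_beta must be finite")
    b = np.array([e.beta_xy for e in estimates])
    w = np.array([e.weight for e in estimates])
    q = w * (b - reference_beta) ** 2
    p = stats.chi2.sf(q, df=1)
    return np.minimum(1.0, penalty_mult * p)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def robust_fit(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    include_intercept: bool = False,
    c: float = TUKEY_C,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> RobustFit:
    """Tukey-bisquare IRLS on a weighted simple regression.

    The scale is re-estimated each iteration as MAD(sqrt(w) * residual) / 0.6745.
    Convergence: maximum coefficient change below ``tol`` (or ``max_iter``
    reached, in which case the last iterate is returned flagged unconverged).
    A vanishing scale means an exact fit; robust weights are then all 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    p = 2 if include_intercept else 1
    if n < p:
        raise EstimationError(f"need at least {p} points, got {n}")
    if np.any(w <= 0):
        raise EstimationError("weights must be positive")
    X = np.column_stack([np.ones(n), x]) if include_intercept else x[:, None]
    coef = _wls(X, y, w)
    rw = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ coef
        wresid = np.sqrt(w) * resid
        scale = float(np.median(np.abs(wresid))) / 0.6745
        if scale < 1e-14:
            # majority of points fit exactly: keep them, reject any point
            # whose residual is materially nonzero, and refit once
            tol_r = 1e-12 * max(1.0, float(np.max(np.abs(wresid))))
            rw = (np.abs(wresid) <= tol_r).astype(float)
            if rw.sum() >= p:
                coef = _wls(X[rw > 0], y[rw > 0], w[rw > 0])
            converged = True
            break
        u = wresid / (c * scale)
        rw = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if np.all(rw == 0):  # pathological: everything rejected; keep last fit
            logger.warning("robust_fit: all points downweighted to zero")
            break
        new = _wls(X, y, w * rw)
        delta = float(np.max(np.abs(new - coef)))
        coef = new
        if delta < tol:
            converged = True
            break
    else:
        it = max_iter
    if not converged:
        logger.warning("robust_fit: no convergence after %d iterations", max_iter)
    resid = y - X @ coef
    scale = float(np.median(np.abs(np.sqrt(w) * resid))) / 0.6745
    return RobustFit(
        coefficients=coef, robust_weights=rw, scale=scale,
        converged=converged, n_iter=it,
    )


def _pooled(
    estimates: Sequence[WaldEstimate],
    penalized: bool,
    robust: bool,
    penalty_mult: float,
) -> PooledEstimate:
    if len(estimates) == 0:
        raise EstimationError("at least one Wald estimate is required")
    b = np.array([e.beta_xy for e in estimates])
    w = np.array([e.weight for e in estimates])
    ids = tuple(e.variant_id for e in estimates)
    n = len(b)

    ivw_beta = float(np.sum(w * b) / np.sum(w))
    f = penalty_factors(estimates, ivw_beta, penalty_mult) if penalized else np.ones(n)

    converged = True
    if robust:
        # Ratio form of the through-origin regression of beta_y on beta_x with
        # weights f / se_y^2: identical weighted residuals, identical slope.
        # Variants whose penalty factor underflowed to exactly zero carry no
        # weight and are held out of the IRLS (which requires positive weights).
        wf = w * f
        active = wf > 0
        if not active.any():
            logger.warning("all penalty factors underflowed to zero; "
                           "falling back to unpenalized weights")
            f = np.ones(n)
            wf = w * f
            active = wf > 0
        fit = robust_fit(np.ones(int(active.sum())), b[active], wf[active],
                         include_intercept=False)
        beta = float(fit.coefficients[0])
        rw = np.zeros(n)
        rw[active] = fit.robust_weights
        converged = fit.converged
    else:
        beta = float(np.sum(w * f * b) / np.sum(w * f))
        rw = np.ones(n)

    se_fixed = float(np.sum(w * f)) ** -0.5
    if (penalized or robust) and n > 1:
        # multiplicative random-effects: inflate the fixed-effect SE when the
        # weighted fit is overdispersed, never deflate it
        sigma = math.sqrt(float(np.sum(w * f * rw * (b - beta) ** 2)) / (n - 1))
        se = se_fixed * max(1.0, sigma)
    else:
        sigma = float("nan")
        se = se_fixed
    pvalue = 2.0 * stats.norm.sf(abs(beta / se))
    method = "ivw" + ("_penalized" if penalized else "") + ("_robust" if robust else "")
    return PooledEstimate(
        method=method, beta=beta, se=se, pvalue=float(pvalue),
        n_variants=n, variant_ids=ids,
        penalty_factors=f, robust_weights=rw,
        residual_scale=sigma, converged=converged,
    )


def ivw(estimates: Sequence[WaldEstimate]) -> PooledEstimate:
    """Fixed-effect inverse-variance weighted pooling of Wald ratios."""
    return _pooled(estimates, penalized=False, robust=False,
                   penalty_mult=DEFAULT_PENALTY_MULT)


def ivw_penalized(
    estimates: Sequence[WaldEstimate],
    penalty_mult: float = DEFAULT_PENALTY_MULT,
) -> PooledEstimate:
    return _pooled(estimates, penalized=True, robust=False, penalty_mult=penalty_mult)


def ivw_robust(estimates: Sequence[WaldEstimate]) -> PooledEstimate:
    return _pooled(estimates, penalized=False, robust=True,
                   penalty_mult=DEFAULT_PENALTY_MULT)


def penalized_robust_ivw(
    estimates: Sequence[WaldEstimate],
    penalty_mult: float = DEFAULT_PENALTY_MULT,
) -> PooledEstimate:
    """Penalized robust IVW: heterogeneity-penalized weights + Tukey loss."""
    return _pooled(estimates, penalized=True, robust=True, penalty_mult=penalty_mult)


ivw_penalized_robust = penalized_robust_ivw


def pool(
    estimates: Sequence[WaldEstimate],
    method: str = "ivw_penalized_robust",
    penalty_mult: float = DEFAULT_PENALTY_MULT,
) -> PooledEstimate:
    """Dispatch to an IVW-family estimator by name (see ``POOL_METHODS``)."""
    if method not in POOL_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {POOL_METHODS}")
    return _pooled(
        estimates,
        penalized="penalized" in method,
        robust="robust" in method,
        penalty_mult=penalty_mult,
    )


def cochran_q(
    estimates: Sequence[WaldEstimate],
    reference_beta: Optional[float] = None,
) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of the Wald ratios about the IVW estimate."""
    if len(estimates) < 2:
        raise EstimationError("Cochran's Q requires at least 2 estimates")
    b = np.array([e.beta_xy for e in estimates])
    w = np.array([e.weight for e in estimates])
    ref = float(np.sum(w * b) / np.sum(w)) if reference_beta is None else reference_beta
    contrib = w * (b - ref) ** 2
    q = float(np.sum(contrib))
    df = len(b) - 1
    return HeterogeneityResult(
        q_total=q, df=df, pvalue=float(stats.chi2.sf(q, df=df)),
        q_contributions=contrib,
        variant_ids=tuple(e.variant_id for e in estimates),
    )


def egger_regression(
    variants: Sequence[HarmonizedVariant],
    penalized: bool = True,
    robust: bool = True,
    penalty_mult: float = DEFAULT_PENALTY_MULT,
    se_method: str = "delta",
) -> EggerResult:
    """MR-Egger weighted regression with an unconstrained intercept.

    Every variant is first oriented so its exposure beta is non-negative
    (negating both betas where needed), making the result invariant to the
    arbitrary allele coding of the input.  Weights are se_y^-2, multiplied by
    heterogeneity penalty factors (against the plain IVW reference) when
    ``penalized``, under a Tukey bisquare loss when ``robust``.  Inference
    uses a t distribution with n - 2 degrees of freedom and a multiplicative
    overdispersion factor max(1, residual scale) on the standard errors.
    """
    n = len(variants)
    if n < 3:
        raise EstimationError(f"MR-Egger requires at least 3 variants, got {n}")
    bx = np.array([v.beta_exposure for v in variants])
    by = np.array([v.beta_outcome for v in variants])
    sy = np.array([v.se_outcome for v in variants])
    if np.any(bx == 0):
        bad = [v.variant_id for v in variants if v.beta_exposure == 0]
        raise EstimationError(f"zero exposure beta for {bad}; invalid instrument(s)")
    sign = np.sign(bx)
    x = bx * sign
    y = by * sign
    if np.ptp(x) < 1e-14:
        raise EstimationError(
            "all exposure betas equal after orientation; Egger design is degenerate")
    w = sy ** -2.0
    if penalized:
        ests = wald_ratios(variants, se_method=se_method)
        ref = float(np.sum([e.weight * e.beta_xy for e in ests])
                    / np.sum([e.weight for e in ests]))
        f = penalty_factors(ests, ref, penalty_mult)
    else:
        f = np.ones(n)

    X = np.column_stack([np.ones(n), x])
    if robust:
        wf = w * f
        active = wf > 0
        if active.sum() < 3:
            raise EstimationError(
                "fewer than 3 instruments retain weight after penalization")
        fit = robust_fit(x[active], y[active], wf[active], include_intercept=True)
        coef = fit.coefficients
        rw = np.zeros(n)
        rw[active] = fit.robust_weights
    else:
        coef = _wls(X, y, w * f)
        rw = np.ones(n)

    weff = w * f * rw
    resid = y - X @ coef
    dof = n - 2
    sigma = math.sqrt(float(np.sum(weff * resid ** 2)) / dof)
    xtwx = X.T @ (weff[:, None] * X)
    cov = max(1.0, sigma) ** 2 * np.linalg.inv(xtwx)
    i_se, s_se = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    tq = stats.t.ppf(0.975, dof)
    intercept, slope = float(coef[0]), float(coef[1])
    return EggerResult(
        intercept=intercept,
        intercept_se=i_se,
        intercept_ci_low=intercept - tq * i_se,
        intercept_ci_high=intercept + tq * i_se,
        intercept_p=float(2.0 * stats.t.sf(abs(intercept / i_se), dof)),
        slope=slope,
        slope_se=s_se,
        slope_p=float(2.0 * stats.t.sf(abs(slope / s_se), dof)),
        residual_scale=sigma,
        n_variants=n,
        penalty_factors=f,
        robust_weights=rw,
    )
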