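"""Two-sample MR estimators and sensitivity statistics.

All estimators consume a harmonised instrument set and return causal-effect
estimates on the outcome's beta scale (log-odds, read as log risk ratio for a
rare binary outcome). Implemented methods:

* Wald ratio — single-instrument estimate with first-order delta-method SE.
* IVW — weighted regression of outcome on exposure betas through the origin
  with weights 1/se_out^2; residual dispersion may inflate but never deflate
  the SE (multiplicative ``max(sigma_hat, 1)`` on the fixed-effect SE).
* MR-Egger — the same regression with a free intercept; the intercept tests
  directional horizontal pleiotropy; SEs carry a ``max(sigma_hat, 1)``
  dispersion multiplier.
* Maximum likelihood — joint normal likelihood over per-instrument true
  effects and the causal slope; the likelihood-ratio statistic against the
  saturated model is the heterogeneity test.
* Cochran's Q — classical fixed-effect heterogeneity statistic.

Confidence intervals are symmetric normal at 95% and p-values are two-sided
normal throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .gwas_data import HarmonisedInstrument, TraitInfo

#: 95% normal CI multiplier, Phi^{-1}(0.975)
Z95 = 1.959964

_PVAL_FLOOR = 5e-324  # smallest subnormal double; keeps pvals in (0, 1]


class EstimationError(RuntimeError):
    """An estimator could not produce a result (degenerate input, no fit)."""


class InsufficientInstrumentsError(EstimationError):
    """Fewer instruments than the method requires (e.g. Egger needs >= 3)."""


def _two_sided_p(beta: float, se: float) -> float:
    return max(float(2 * stats.norm.sf(abs(beta) / se)), _PVAL_FLOOR)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the outcome beta scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, nsnp: int) -> "MREstimate":
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=beta - Z95 * se,
            ci_high=beta + Z95 * se,
            pval=_two_sided_p(beta, se),
            nsnp=nsnp,
        )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the intercept-based pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass(frozen=True)
class HeterogeneityResult:
    """A chi-square heterogeneity test over the instrument set."""

    method: str  # cochran_q_ivw | lrt_ml
    stat: float
    df: int
    pval: float


@dataclass(frozen=True)
class MRInput:
    """Exposure/outcome traits plus their usable harmonised instruments."""

    exposure: TraitInfo
    outcome: TraitInfo
    instruments: tuple[HarmonisedInstrument, ...]

    def __init__(
        self,
        exposure: TraitInfo,
        outcome: TraitInfo,
        instruments: Sequence[HarmonisedInstrument],
    ):
        instruments = tuple(instruments)
        if not instruments:
            raise ValueError("MRInput requires at least one instrument")
        if any(not i.usable for i in instruments):
            raise ValueError("dropped instruments must be excluded from MRInput")
        object.__setattr__(self, "exposure", exposure)
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "instruments", instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([i.exposure_beta for i in self.instruments])
        sx = np.array([i.exposure_se for i in self.instruments])
        by = np.array([i.outcome_beta for i in self.instruments])
        sy = np.array([i.outcome_se for i in self.instruments])
        return bx, sx, by, sy

    @property
    def nsnp(self) -> int:
        return len(self.instruments)


# ---------------------------------------------------------------------------
# Estimators


def wald_ratio(inst: HarmonisedInstrument) -> MREstimate:
    """Single-instrument causal estimate: outcome beta over exposure beta."""
    if inst.exposure_beta == 0:
        raise EstimationError(
            f"{inst.variant_id}: Wald ratio undefined for zero exposure beta"
        )
    beta = inst.outcome_beta / inst.exposure_beta
    se = inst.outcome_se / abs(inst.exposure_beta)
    return MREstimate.from_beta_se("wald_ratio", beta, se, nsnp=1)


def ivw(mr_input: MRInput) -> MREstimate:
    """Inverse-variance weighted estimate over >= 2 instruments.

    A singleton input delegates to :func:`wald_ratio`. With dispersion
    sigma_hat estimated from the weighted residuals, the SE is the
    fixed-effect SE times ``max(sigma_hat, 1)`` — under-dispersion never
    shrinks the SE below the fixed-effect value.
    """
    if mr_input.nsnp == 1:
        return wald_ratio(mr_input.instruments[0])
    bx, _, by, sy = mr_input.arrays()
    if np.all(bx == 0):
        raise EstimationError("all exposure betas are zero; IVW undefined")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by) / sxx)
    k = mr_input.nsnp
    resid = by - beta * bx
    sigma2 = float(np.sum(w * resid**2) / (k - 1))
    se = max(math.sqrt(sigma2), 1.0) / math.sqrt(sxx)
    return MREstimate.from_beta_se("ivw", beta, se, nsnp=k)


def egger(mr_input: MRInput) -> EggerResult:
    """MR-Egger regression (weighted, free intercept) over >= 3 instruments."""
    if mr_input.nsnp < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {mr_input.nsnp}"
        )
    bx, _, by, sy = mr_input.arrays()
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    A = X.T @ (w[:, None] * X)
    try:
        cov_unscaled = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular design in MR-Egger regression") from exc
    coef = cov_unscaled @ (X.T @ (w * by))
    k = mr_input.nsnp
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    scale = max(math.sqrt(sigma2), 1.0)
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    slope = MREstimate.from_beta_se("egger", float(coef[1]), float(ses[1]), nsnp=k)
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_pval=_two_sided_p(float(coef[0]), float(ses[0])),
    )


def _profile_rss(theta: float, bx, sx, by, sy) -> float:
    # profile -2 log-likelihood (up to a constant): per-instrument true
    # effects maximised analytically
    v = sy**2 + theta**2 * sx**2
    return float(np.sum((by - theta * bx) ** 2 / v))


def max_likelihood(mr_input: MRInput) -> tuple[MREstimate, HeterogeneityResult]:
    """Maximum-likelihood causal estimate with an LRT heterogeneity test.

    The joint model treats observed exposure and outcome betas as normal
    around per-instrument true effects xi_i and theta * xi_i; profiling the
    xi_i analytically reduces the fit to a one-dimensional minimisation of
    ``sum (by - theta*bx)^2 / (sy^2 + theta^2 sx^2)``. The SE comes from the
    curvature (observed information) of the profile likelihood; the
    heterogeneity statistic is twice the log-likelihood gap to the saturated
    model (which fits every instrument exactly), on nsnp - 1 degrees of
    freedom.
    """
    if mr_input.nsnp < 2:
        raise InsufficientInstrumentsError("maximum likelihood requires >= 2 instruments")
    bx, sx, by, sy = mr_input.arrays()
    if np.all(bx == 0):
        raise EstimationError("all exposure betas are zero; ML undefined")
    w = 1.0 / sy**2
    theta0 = float(np.sum(w * bx * by) / np.sum(w * bx * bx))  # IVW start

    res = optimize.minimize_scalar(
        _profile_rss, bracket=(theta0 - 0.5, theta0 + 0.5), args=(bx, sx, by, sy)
    )
    if not np.isfinite(res.x) or not np.isfinite(res.fun):
        raise EstimationError(f"ML optimisation failed: {res}")
    theta = float(res.x)

    h = 1e-4 * (1.0 + abs(theta))
    q0 = _profile_rss(theta, bx, sx, by, sy)
    qpp = (
        _profile_rss(theta + h, bx, sx, by, sy)
        - 2 * q0
        + _profile_rss(theta - h, bx, sx, by, sy)
    ) / h**2
    if qpp <= 0:
        raise EstimationError(
            f"non-positive profile curvature at theta={theta:.4g} (qpp={qpp:.4g})"
        )
    se = math.sqrt(2.0 / qpp)
    estimate = MREstimate.from_beta_se("max_likelihood", theta, se, nsnp=mr_input.nsnp)
    stat = max(q0, 0.0)
    df = mr_input.nsnp - 1
    het = HeterogeneityResult(
        method="lrt_ml", stat=stat, df=df, pval=float(stats.chi2.sf(stat, df))
    )
    return estimate, het


def cochran_q(mr_input: MRInput) -> HeterogeneityResult:
    """Cochran's Q over per-instrument Wald ratios against the fixed-effect IVW."""
    if mr_input.nsnp < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    bx, _, by, sy = mr_input.arrays()
    if np.any(bx == 0):
        raise EstimationError("Cochran's Q undefined with zero exposure betas")
    ratios = by / bx
    w = (bx / sy) ** 2
    beta_fixed = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta_fixed) ** 2))
    df = mr_input.nsnp - 1
    return HeterogeneityResult(
        method="cochran_q_ivw", stat=q, df=df, pval=float(stats.chi2.sf(q, df))
    )


def to_risk_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-risk estimate and its CI bounds into risk ratios."""
    return math.exp(est.beta), math.exp(est.ci_low), math.exp(est.ci_high)
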