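"""Two-sample Mendelian randomization estimators.

Per-variant Wald ratios, fixed-effect (inverse-variance weighted) pooling
with Cochran's Q heterogeneity, leave-one-out outlier diagnosis, Egger
regression as the pleiotropy-robust sensitivity analysis, and a closed-form
post-hoc power approximation for binary outcomes.

All effects are log-odds ratios; ``theta`` is the causal log-odds ratio of
the outcome per log-odds unit of the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonizedPair

__all__ = [
    "WaldEstimate",
    "MRFit",
    "EggerFit",
    "LeaveOneOutResult",
    "PowerResult",
    "wald_ratio",
    "wald_ratios",
    "ivw_fixed",
    "cochran_q",
    "leave_one_out",
    "egger",
    "mr_power",
]

#: residual heterogeneity p-value above which a removed variant counts as
#: having explained the heterogeneity
OUTLIER_RESIDUAL_P = 0.05

#: p-values below this are formatted as "<2.2e-308" in text output
P_FLOOR = 2.2e-308


class MREstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass
class WaldEstimate:
    """Single-variant causal ratio estimate with its standard error."""

    rsid: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.se_theta)):
            raise MREstimationError(f"{self.rsid}: non-finite Wald estimate")
        if self.se_theta <= 0:
            raise MREstimationError(f"{self.rsid}: se must be positive")


@dataclass
class MRFit:
    """Pooled fixed-effect MR result with heterogeneity statistics."""

    theta_hat: float
    se: float
    p: float
    q: float
    df: int
    p_het: float
    k: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta_hat))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.exp(self.theta_hat - 1.96 * self.se)
        hi = np.exp(self.theta_hat + 1.96 * self.se)
        return float(lo), float(hi)


@dataclass
class EggerFit:
    """Egger regression of outcome on exposure effects with a free intercept."""

    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    k: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.slope))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.exp(self.slope - 1.96 * self.slope_se)
        hi = np.exp(self.slope + 1.96 * self.slope_se)
        return float(lo), float(hi)


def wald_ratio(
    b_out: float,
    se_out: float,
    b_exp: float,
    se_exp: float,
    order: str = "first",
    rsid: str = "",
) -> WaldEstimate:
    """Per-variant causal ratio theta = b_out / b_exp.

    ``order`` selects the delta-method standard error: first-order
    se_out/|b_exp| (default) or second-order, which adds the exposure-error
    term b_out²·se_exp²/b_exp⁴.
    """
    if b_exp == 0:
        raise MREstimationError(f"{rsid or 'variant'}: exposure effect is zero, ratio undefined")
    theta = b_out / b_exp
    if order == "first":
        se = se_out / abs(b_exp)
    elif order == "second":
        se = np.sqrt(se_out**2 / b_exp**2 + b_out**2 * se_exp**2 / b_exp**4)
    else:
        raise ValueError(f"unknown Wald se order {order!r}")
    return WaldEstimate(rsid=rsid, theta=float(theta), se_theta=float(se))


def wald_ratios(pairs: Sequence[HarmonizedPair], order: str = "first") -> list[WaldEstimate]:
    """Wald ratios for all non-dropped harmonized pairs with b_exp != 0."""
    out = []
    for p in pairs:
        if p.dropped or p.beta_exp == 0:
            continue
        out.append(wald_ratio(p.beta_out, p.se_out, p.beta_exp, p.se_exp,
                              order=order, rsid=p.rsid))
    return out


def _weights(estimates: Sequence[WaldEstimate]) -> np.ndarray:
    return np.array([1.0 / e.se_theta**2 for e in estimates])


def ivw_fixed(estimates: Sequence[WaldEstimate]) -> MRFit:
    """Fixed-effect inverse-variance-weighted pooling of Wald ratios.

    Heterogeneity (Cochran's Q) is attached when k >= 2; with a single
    instrument Q is 0 on 0 df and p_het is undefined (NaN).
    """
    k = len(estimates)
    if k == 0:
        raise MREstimationError("cannot pool an empty set of estimates")
    w = _weights(estimates)
    theta = np.array([e.theta for e in estimates])
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(theta_hat) / se))
    if k >= 2:
        q, df, p_het = cochran_q(estimates, theta_hat)
    else:
        q, df, p_het = 0.0, 0, float("nan")
    return MRFit(theta_hat=theta_hat, se=se, p=p, q=q, df=df, p_het=p_het, k=k)


def cochran_q(estimates: Sequence[WaldEstimate], theta_hat: float) -> tuple[float, int, float]:
    """Cochran's Q = sum_i w_i (theta_i − theta_hat)², chi-square on k−1 df."""
    k = len(estimates)
    if k < 2:
        raise MREstimationError("heterogeneity undefined for fewer than 2 instruments")
    w = _weights(estimates)
    theta = np.array([e.theta for e in estimates])
    q = float(np.sum(w * (theta - theta_hat) ** 2))
    df = k - 1
    p_het = float(stats.chi2.sf(q, df))
    return q, df, p_het


@dataclass
class LeaveOneOutResult:
    """Per-variant leave-one-out refits and the outlier diagnosis.

    ``dominant`` is the variant whose removal reduces Q the most;
    ``outlier`` equals ``dominant`` only when the residual heterogeneity
    p-value after its removal exceeds ``residual_p_threshold`` (i.e. the
    single variant explains the heterogeneity), else None.
    """

    fits: dict[str, MRFit]
    dominant: str
    outlier: str | None
    q_full: float
    residual_p_threshold: float


def leave_one_out(
    estimates: Sequence[WaldEstimate],
    residual_p_threshold: float = OUTLIER_RESIDUAL_P,
) -> LeaveOneOutResult:
    """Refit the pooled model leaving each variant out in turn."""
    k = len(estimates)
    if k < 3:
        raise MREstimationError("leave-one-out needs at least 3 instruments")
    full = ivw_fixed(list(estimates))
    fits: dict[str, MRFit] = {}
    best_rsid, best_q = None, np.inf
    for i, e in enumerate(estimates):
        rest = [x for j, x in enumerate(estimates) if j != i]
        fit = ivw_fixed(rest)
        fits[e.rsid] = fit
        if fit.q < best_q:
            best_q, best_rsid = fit.q, e.rsid
    outlier = best_rsid if fits[best_rsid].p_het > residual_p_threshold else None
    return LeaveOneOutResult(fits=fits, dominant=best_rsid, outlier=outlier,
                             q_full=full.q, residual_p_threshold=residual_p_threshold)


def egger(pairs: Sequence[HarmonizedPair]) -> EggerFit:
    """Egger regression MR: weighted regression of outcome on exposure effects
    with a free intercept (average directional pleiotropy).

    Each pair is first oriented so that the exposure effect is positive (the
    method's defining sign convention); weights are 1/se_out²; inference uses
    the t distribution with k−2 df.
    """
    usable = [p for p in pairs if not p.dropped and p.beta_exp != 0]
    k = len(usable)
    if k < 3:
        raise MREstimationError("Egger regression needs at least 3 instruments")
    sign = np.array([np.sign(p.beta_exp) for p in usable])
    bx = np.array([p.beta_exp for p in usable]) * sign
    by = np.array([p.beta_out for p in usable]) * sign
    se_out = np.array([p.se_out for p in usable])
    if np.allclose(bx, bx[0]):
        raise MREstimationError("degenerate design: all exposure effects equal after orientation")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / se_out**2).fit()
    # statsmodels' default covariance already uses the t(k-2) reference
    return EggerFit(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        slope_p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        intercept_p=float(fit.pvalues[0]),
        k=k,
    )


@dataclass
class PowerResult:
    power: float
    alpha: float
    k: int
    variance_explained: float
    n_cases: int
    n_controls: int
    true_or: float
    detectable_or: float  # smallest OR detectable at 80% power


def mr_power(
    k: int,
    variance_explained: float,
    n_cases: int,
    n_controls: int,
    true_or: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> PowerResult:
    """Approximate power of a two-sample MR analysis with a binary outcome.

    Uses the two-sided normal approximation with non-centrality
    b = |log OR| · sqrt(N·R²·phi(1−phi)),
    power = Phi(−z_{1−alpha/2} + b) + Phi(−z_{1−alpha/2} − b),
    where N is the total outcome sample size and phi its case fraction (so
    power equals alpha exactly at the null OR = 1). The same expression is
    inverted (dropping the negligible second term) for the smallest OR
    detectable at ``target_power``.
    """
    if not (0 < variance_explained < 1):
        raise ValueError("variance_explained must be in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    n_eff = n_cases + n_controls
    phi = n_cases / n_eff
    scale = np.sqrt(n_eff * variance_explained * phi * (1 - phi))
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    b = abs(np.log(true_or)) * scale
    power = float(stats.norm.cdf(-z_alpha + b) + stats.norm.cdf(-z_alpha - b))
    z_power = stats.norm.ppf(target_power)
    detectable = float(np.exp((z_alpha + z_power) / scale))
    return PowerResult(power=power, alpha=alpha, k=k,
                       variance_explained=variance_explained,
                       n_cases=n_cases, n_controls=n_controls,
                       true_or=true_or, detectable_or=detectable)


def format_p(p: float) -> str:
    """Render a p-value, flooring below-double-precision values."""
    if np.isnan(p):
        return "NA"
    if p < P_FLOOR:
        return "<2.2e-308"
    return f"{p:.3g}"
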