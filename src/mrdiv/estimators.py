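"""Variant-level Wald ratios and the classical MR combiners.

For variant j with exposure effect beta_x_j (SD units of the exposure) and
outcome effect beta_y_j (log-odds of disease), the Wald ratio

    theta_j = beta_y_j / beta_x_j,   v_j = se(beta_y_j)^2 / beta_x_j^2

is the per-variant causal estimate with its first-order variance.  The
combiners implemented here are:

* inverse-variance weighted (IVW) mean of the ratios, with either a
  fixed-effect SE or a multiplicative random-effects SE inflated by
  sqrt(Q/(J-1)) when the ratios are overdispersed;
* the weighted median (consistent when valid instruments carry more than
  half the weight), with a parametric-bootstrap SE;
* MR-Egger: weighted regression of beta_y on beta_x with a free intercept
  estimating average directional pleiotropy.

Estimates are reported on both the log-odds and odds-ratio scales with
95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedPanel, HarmonizedVariant

Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class WaldEstimate:
    rsid: str
    theta: float
    variance: float


@dataclass
class CausalEstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_: float
    or_low: float
    or_high: float
    n_variants: int
    egger_intercept: float | None = None
    egger_intercept_ci: tuple[float, float] | None = None
    egger_intercept_p: float | None = None

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": self.or_,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "n_variants": self.n_variants,
        }
        if self.egger_intercept is not None:
            d["egger_intercept"] = self.egger_intercept
            d["egger_intercept_ci"] = list(self.egger_intercept_ci)
            d["egger_intercept_p"] = self.egger_intercept_p
        return d


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its 95% Wald interval."""
    if se <= 0:
        raise ValueError("SE must be positive")
    return (
        math.exp(beta),
        math.exp(beta - Z95 * se),
        math.exp(beta + Z95 * se),
    )


def _finish(method: str, beta: float, se: float, pvalue: float, n: int, **extra) -> CausalEstimate:
    if se == 0:  # exact fit (degenerate, noise-free inputs)
        or_ = math.exp(beta)
        or_low = or_high = or_
    else:
        or_, or_low, or_high = to_odds_ratio(beta, se)
    return CausalEstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=pvalue,
        or_=or_,
        or_low=or_low,
        or_high=or_high,
        n_variants=n,
        **extra,
    )


def wald_ratio(v: HarmonizedVariant) -> WaldEstimate:
    if v.beta_x == 0:
        raise ZeroDivisionError(f"{v.rsid}: zero exposure effect, ratio undefined")
    return WaldEstimate(
        rsid=v.rsid,
        theta=v.beta_y / v.beta_x,
        variance=v.se_y**2 / v.beta_x**2,
    )


def wald_estimates(panel: HarmonizedPanel) -> list[WaldEstimate]:
    return [wald_ratio(v) for v in panel.variants]


def ivw(estimates: list[WaldEstimate], model: str = "auto") -> CausalEstimate:
    """Inverse-variance weighted average of Wald ratios.

    The point estimate sum(w theta)/sum(w) with w = 1/v is identical under
    every model; only the SE differs.  ``fixed`` uses (sum w)^-1/2;
    ``multiplicative_random`` inflates it by max(1, sqrt(Q/(J-1)));
    ``auto`` applies the fixed SE for J < 4 and the multiplicative
    random-effects SE otherwise.
    """
    if not estimates:
        raise ValueError("IVW needs at least one Wald estimate")
    if model not in ("fixed", "multiplicative_random", "auto"):
        raise ValueError(f"unknown IVW model {model!r}")
    theta = np.array([e.theta for e in estimates])
    w = 1.0 / np.array([e.variance for e in estimates])
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    J = len(estimates)
    if model == "auto":
        model = "fixed" if J < 4 else "multiplicative_random"
    if model == "multiplicative_random" and J > 1:
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (J - 1)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return _finish("IVW", beta, se, p, J)


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median with the cumulative standardized-weight interpolation

    p_j = (S_j - w_j/2) / S_J on sorted ratios, linearly interpolated at 1/2.
    """
    order = np.argsort(theta)
    theta = theta[order]
    w = w[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    if 0.5 <= p[0]:
        return float(theta[0])
    if 0.5 >= p[-1]:
        return float(theta[-1])
    k = int(np.searchsorted(p, 0.5, side="right")) - 1
    frac = (0.5 - p[k]) / (p[k + 1] - p[k])
    return float(theta[k] + frac * (theta[k + 1] - theta[k]))


def weighted_median(
    estimates: list[WaldEstimate], n_boot: int = 10_000, seed: int | None = None
) -> CausalEstimate:
    """Weighted median of Wald ratios; SE by parametric bootstrap.

    Each bootstrap replicate redraws theta_j ~ Normal(theta_j, v_j) and
    recomputes the weighted median; the SE is the standard deviation of the
    replicates.
    """
    if len(estimates) < 3:
        raise ValueError("weighted median needs at least three estimates")
    theta = np.array([e.theta for e in estimates])
    var = np.array([e.variance for e in estimates])
    w = 1.0 / var
    beta = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, np.sqrt(var), size=(n_boot, len(theta)))
    order = np.argsort(draws, axis=1)
    th = np.take_along_axis(draws, order, axis=1)
    ww = np.broadcast_to(w, draws.shape)
    ww = np.take_along_axis(ww, order, axis=1)
    s = np.cumsum(ww, axis=1)
    p = (s - 0.5 * ww) / s[:, -1:]
    boot = np.empty(n_boot)
    for i in range(n_boot):  # rows have distinct sort orders; interp per row
        boot[i] = np.interp(0.5, p[i], th[i])
    se = float(np.std(boot, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return _finish("weighted_median", beta, se, pval, len(estimates))


def mr_egger(panel: HarmonizedPanel) -> CausalEstimate:
    """MR-Egger regression with its intercept (directional pleiotropy) test.

    Every variant is first oriented so beta_x >= 0 (negating both effects
    when needed), without which the intercept is not identified.  beta_y is
    regressed on beta_x with weights 1/se_y^2; SEs carry a multiplicative
    overdispersion factor max(1, residual SE), and p-values use a t
    reference with J - 2 degrees of freedom.
    """
    if len(panel.variants) < 3:
        raise ValueError("MR-Egger needs at least three variants")
    bx = np.array([v.beta_x for v in panel.variants])
    by = np.array([v.beta_y for v in panel.variants])
    sey = np.array([v.se_y for v in panel.variants])
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    if np.ptp(bx) == 0:
        raise ValueError("no spread in exposure effects: Egger design singular")

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sey**2).fit()
    sigma = math.sqrt(fit.scale)
    # statsmodels' SEs already include sigma; dividing by min(1, sigma)
    # leaves the max(1, sigma) multiplicative inflation over the fixed SE
    infl = min(1.0, sigma) if sigma > 0 else 1.0
    se_int, se_slope = fit.bse / infl
    intercept, slope = fit.params
    df = len(bx) - 2
    t_low = float(stats.t.ppf(0.975, df))
    p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df))
    return _finish(
        "MR_Egger",
        float(slope),
        float(se_slope),
        p_slope,
        len(bx),
        egger_intercept=float(intercept),
        egger_intercept_ci=(
            float(intercept - t_low * se_int),
            float(intercept + t_low * se_int),
        ),
        egger_intercept_p=p_int,
    )
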