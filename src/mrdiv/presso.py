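"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier tests.

The global test measures how far the observed outcome effects sit from
what the exposure effects predict under a single causal slope.  For each
variant j the slope is re-estimated leaving that variant out
(theta_loo_j), and the observed statistic is the weighted residual sum of
squares

    RSS_obs = sum_j w_j (beta_y_j - theta_loo_j * beta_x_j)^2,  w_j = 1/se_y_j^2.

Its null distribution is built by parametric simulation: each replicate
redraws beta_x*_j ~ N(beta_x_j, se_x_j^2) and
beta_y*_j ~ N(theta_loo_j * beta_x_j, se_y_j^2), then recomputes the RSS
(including the leave-one-out slopes) on the simulated panel.  The global
p-value is the add-one empirical tail probability.

The outlier test compares each variant's observed weighted squared
residual against its own simulated distribution, Bonferroni-adjusts the
per-variant empirical p-values by the panel size, and reports flagged
variants together with the IVW estimate recomputed without them.

Simulation draws are generated from independent substreams keyed by rsid
and the master seed, so results do not depend on variant order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .estimators import CausalEstimate, ivw, wald_estimates
from .harmonize import HarmonizedPanel


@dataclass
class PressoResult:
    rss_observed: float
    global_p: float
    n_sim: int
    seed: int
    n_variants: int
    outliers: list[tuple[str, float]] = field(default_factory=list)
    outlier_pvalues: dict[str, float] = field(default_factory=dict)
    corrected_estimate: CausalEstimate | None = None

    @property
    def outlier_rsids(self) -> list[str]:
        return [r for r, _ in self.outliers]


def _variant_rng(seed: int, rsid: str) -> np.random.Generator:
    # independent, order-invariant substream per variant
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(rsid.encode())])
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (weighted regression through the origin).

    Works on 1-D panels or on (n_sim, J) simulated panels; the slope for
    column j omits column j from the weighted sums.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _observed(panel: HarmonizedPanel):
    bx = np.array([v.beta_x for v in panel.variants])
    by = np.array([v.beta_y for v in panel.variants])
    sex = np.array([v.se_x for v in panel.variants])
    sey = np.array([v.se_y for v in panel.variants])
    w = 1.0 / sey**2
    theta_loo = _loo_slopes(bx, by, w)
    resid2 = w * (by - theta_loo * bx) ** 2
    return bx, by, sex, sey, w, theta_loo, resid2


def _simulated_residuals(panel: HarmonizedPanel, n_sim: int, seed: int):
    """(n_sim, J) matrix of simulated weighted squared residuals."""
    bx, by, sex, sey, w, theta_loo, _ = _observed(panel)
    J = len(bx)
    bx_star = np.empty((n_sim, J))
    by_star = np.empty((n_sim, J))
    for j, v in enumerate(panel.variants):
        rng = _variant_rng(seed, v.rsid)
        bx_star[:, j] = rng.normal(bx[j], sex[j], size=n_sim)
        by_star[:, j] = rng.normal(theta_loo[j] * bx[j], sey[j], size=n_sim)
    theta_loo_star = _loo_slopes(bx_star, by_star, w)
    return w * (by_star - theta_loo_star * bx_star) ** 2


def presso_global_test(
    panel: HarmonizedPanel, n_sim: int = 10_000, seed: int = 0
) -> PressoResult:
    """Global heterogeneity (horizontal pleiotropy) test."""
    if len(panel.variants) < 4:
        raise ValueError("PRESSO global test needs at least four variants")
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives an unstable empirical p-value")
    *_, resid2 = _observed(panel)
    rss_obs = float(np.sum(resid2))
    rss_star = np.sum(_simulated_residuals(panel, n_sim, seed), axis=1)
    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        seed=seed,
        n_variants=len(panel.variants),
    )


def presso_outlier_test(
    panel: HarmonizedPanel,
    n_sim: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PressoResult:
    """Per-variant outlier test with Bonferroni adjustment.

    A variant is flagged when its Bonferroni-adjusted empirical p-value
    falls below ``alpha``.  ``corrected_estimate`` is the IVW estimate on
    the panel with flagged variants removed (single exclusion pass); when
    nothing is flagged it equals plain IVW on the full panel.
    """
    if len(panel.variants) < 4:
        raise ValueError("PRESSO outlier test needs at least four variants")
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives an unstable empirical p-value")
    if n_sim * alpha <= len(panel.variants):
        logger.warning(
            "n_sim=%d cannot resolve Bonferroni-adjusted p below alpha=%g for "
            "J=%d variants (smallest attainable adjusted p is J/(n_sim+1)); "
            "no outlier can be flagged",
            n_sim,
            alpha,
            len(panel.variants),
        )
    *_, resid2 = _observed(panel)
    rss_obs = float(np.sum(resid2))
    sim = _simulated_residuals(panel, n_sim, seed)
    global_p = float((1 + np.sum(np.sum(sim, axis=1) >= rss_obs)) / (n_sim + 1))

    J = len(panel.variants)
    p_raw = (1 + np.sum(sim >= resid2, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * J)
    outliers = [
        (panel.variants[j].rsid, float(p_adj[j]))
        for j in range(J)
        if p_adj[j] < alpha
    ]
    flagged = {r for r, _ in outliers}
    kept = panel.subset([r for r in panel.rsids if r not in flagged])
    corrected = ivw(wald_estimates(kept), model="auto")
    corrected.method = "MR_PRESSO"
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        seed=seed,
        n_variants=J,
        outliers=outliers,
        outlier_pvalues={panel.variants[j].rsid: float(p_raw[j]) for j in range(J)},
        corrected_estimate=corrected,
    )
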