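"""Cross-dataset heterogeneity of per-variant causal estimates.

When the same instrument set is applied to two outcome datasets — e.g. a
clinically diagnosed case-control GWAS and a family-history proxy study
(GWAX) — each variant yields two Wald estimators that should agree if both
datasets measure the same outcome.  Disagreement is quantified per variant
with Cochran's Q (inverse-variance weighted, chi-square with k-1 = 1 df)
and I^2 = max(0, (Q - (k-1))/Q) * 100%, banded as low [0, 25), moderate
[25, 50), large [50, 75) and extreme [75, 100].  The systematic shift of
the whole instrument set is tested with a paired-samples t-test of the two
Wald estimator vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import WaldEstimate, wald_estimates
from .harmonize import HarmonizedPanel

I2_BANDS = (
    (25.0, "low"),
    (50.0, "moderate"),
    (75.0, "large"),
    (100.0 + 1e-9, "extreme"),
)


def classify_band(i2: float) -> str:
    if not (0 <= i2 <= 100):
        raise ValueError("I^2 must lie in [0, 100]")
    for upper, name in I2_BANDS:
        if i2 < upper:
            return name
    return "extreme"  # i2 == 100 exactly


@dataclass
class HeterogeneityRecord:
    rsid: str
    theta_a: float
    theta_b: float
    var_a: float
    var_b: float
    q: float
    q_p: float
    i2: float
    band: str


@dataclass
class PairedTTestResult:
    mean_a: float
    mean_b: float
    mean_diff: float
    t_stat: float
    df: int
    pvalue: float
    n: int


def variant_heterogeneity(wald_a: WaldEstimate, wald_b: WaldEstimate) -> HeterogeneityRecord:
    """Two-dataset Cochran's Q and I^2 for one variant.

    With k = 2 the inverse-variance pooled Q reduces to the closed form
    (theta_a - theta_b)^2 / (var_a + var_b).
    """
    if wald_a.rsid != wald_b.rsid:
        raise ValueError("rsid mismatch between the two Wald estimates")
    if wald_a.variance <= 0 or wald_b.variance <= 0:
        raise ValueError("variances must be positive")
    w_a, w_b = 1.0 / wald_a.variance, 1.0 / wald_b.variance
    pooled = (w_a * wald_a.theta + w_b * wald_b.theta) / (w_a + w_b)
    q = w_a * (wald_a.theta - pooled) ** 2 + w_b * (wald_b.theta - pooled) ** 2
    q_p = float(stats.chi2.sf(q, df=1))
    i2 = max(0.0, (q - 1.0) / q * 100.0) if q > 0 else 0.0
    return HeterogeneityRecord(
        rsid=wald_a.rsid,
        theta_a=wald_a.theta,
        theta_b=wald_b.theta,
        var_a=wald_a.variance,
        var_b=wald_b.variance,
        q=float(q),
        q_p=q_p,
        i2=float(i2),
        band=classify_band(i2),
    )


def heterogeneity_table(
    panel_a: HarmonizedPanel,
    panel_b: HarmonizedPanel,
    rsids: Sequence[str] | None = None,
) -> list[HeterogeneityRecord]:
    """Per-variant heterogeneity records over a shared instrument set."""
    wald_a = {e.rsid: e for e in wald_estimates(panel_a)}
    wald_b = {e.rsid: e for e in wald_estimates(panel_b)}
    if rsids is None:
        rsids = [r for r in panel_a.rsids if r in wald_b]
    if len(rsids) == 0:
        raise ValueError("no shared variants to compare")
    missing = [r for r in rsids if r not in wald_a or r not in wald_b]
    if missing:
        raise KeyError(f"variants absent from a panel: {missing[:5]}")
    return [variant_heterogeneity(wald_a[r], wald_b[r]) for r in rsids]


def count_heterogeneous(records: Sequence[HeterogeneityRecord]) -> dict[str, int]:
    """Counts of variants with I^2 strictly above the 25% and 50% bands."""
    return {
        "i2_gt_25": sum(1 for r in records if r.i2 > 25.0),
        "i2_gt_50": sum(1 for r in records if r.i2 > 50.0),
        "n": len(records),
    }


def paired_t_test(thetas_a: Sequence[float], thetas_b: Sequence[float]) -> PairedTTestResult:
    """Paired-samples t-test of two aligned Wald estimator vectors."""
    a = np.asarray(thetas_a, dtype=float)
    b = np.asarray(thetas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("degenerate differences: zero variance")
    t_stat = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    return PairedTTestResult(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        mean_diff=float(np.mean(d)),
        t_stat=t_stat,
        df=n - 1,
        pvalue=p,
        n=n,
    )
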