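"""Wald ratios and the IVW / weighted-median / MR-Egger combiners.

Each combiner is checked against an independently coded brute-force
oracle: plain weighted sums for IVW, cumulative-weight interpolation via
np.interp for the weighted median, and unweighted least squares on
1/se-transformed points for Egger.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrdiv import (
    HarmonizedVariant,
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_estimates,
    wald_ratio,
    weighted_median,
)
from mrdiv.estimators import WaldEstimate, Z95


def _estimates(thetas, variances):
    return [
        WaldEstimate(rsid=f"rs{i}", theta=t, variance=v)
        for i, (t, v) in enumerate(zip(thetas, variances))
    ]


# ---------------------------------------------------------------- Wald ratio

@pytest.mark.parametrize(
    "beta_y, beta_x, se_y, theta, variance",
    [
        (0.01, 0.02, 0.004, 0.5, 0.04),
        (0.0, 0.02, 0.004, 0.0, 0.04),
        (-0.03, 0.03, 0.006, -1.0, 0.04),
    ],
)
def test_wald_ratio_formula(beta_y, beta_x, se_y, theta, variance):
    v = HarmonizedVariant("rs1", beta_x, 0.003, beta_y, se_y)
    est = wald_ratio(v)
    assert est.theta == pytest.approx(theta)
    assert est.variance == pytest.approx(variance)


def test_wald_ratio_zero_exposure_raises():
    with pytest.raises(ZeroDivisionError):
        wald_ratio(HarmonizedVariant("rs1", 0.0, 0.003, 0.01, 0.004))


# ----------------------------------------------------------------------- IVW

def test_ivw_single_estimate_identity():
    e = ivw(_estimates([0.7], [0.09]), model="fixed")
    assert e.beta == pytest.approx(0.7)
    assert e.se == pytest.approx(0.3)


def test_ivw_equal_weight_mean():
    e = ivw(_estimates([0.5, 1.0], [0.04, 0.04]), model="fixed")
    assert e.beta == pytest.approx(0.75)
    assert e.se == pytest.approx(0.141421, abs=1e-6)


def test_ivw_point_estimate_invariant_to_model():
    thetas, variances = [0.2, 0.5, 0.9, -0.1, 0.4], [0.1, 0.05, 0.2, 0.08, 0.12]
    est = _estimates(thetas, variances)
    betas = {m: ivw(est, model=m).beta for m in ("fixed", "multiplicative_random", "auto")}
    assert len({round(b, 15) for b in betas.values()}) == 1
    # random-effects SE never falls below the fixed SE
    assert ivw(est, model="multiplicative_random").se >= ivw(est, model="fixed").se


def test_ivw_duplicated_inputs_halve_fixed_variance():
    est = _estimates([0.2, 0.5, 0.9], [0.1, 0.05, 0.2])
    single, doubled = ivw(est, model="fixed"), ivw(est + est, model="fixed")
    assert doubled.beta == pytest.approx(single.beta, rel=1e-14)
    assert doubled.se == pytest.approx(single.se / math.sqrt(2), rel=1e-12)


def test_ivw_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = rng.integers(1, 7)
        thetas = rng.normal(0, 1, n)
        variances = rng.uniform(0.01, 1.0, n)
        e = ivw(_estimates(thetas, variances), model="fixed")
        w = 1 / variances
        assert e.beta == pytest.approx(float(np.sum(w * thetas) / np.sum(w)), abs=1e-12)
        assert e.se == pytest.approx(float(np.sum(w) ** -0.5), abs=1e-12)


def test_ivw_empty_errors():
    with pytest.raises(ValueError):
        ivw([])


# ----------------------------------------------------------- weighted median

def _median_oracle(thetas, weights):
    """Independent interpolation oracle on cumulative standardized weights."""
    order = np.argsort(thetas)
    t, w = np.asarray(thetas)[order], np.asarray(weights)[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, t))


def test_weighted_median_symmetric_center():
    e = weighted_median(_estimates([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]), n_boot=200, seed=0)
    assert e.beta == pytest.approx(2.0)


def test_weighted_median_robust_to_outlier():
    e = weighted_median(_estimates([1.0, 2.0, 100.0], [1.0, 1.0, 1.0]), n_boot=200, seed=0)
    assert e.beta == pytest.approx(2.0)


@pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_weighted_median_matches_interp_oracle(n, seed):
    rng = np.random.default_rng(seed)
    thetas = rng.normal(0, 2, n)
    variances = rng.uniform(0.05, 2.0, n)
    e = weighted_median(_estimates(thetas, variances), n_boot=100, seed=0)
    assert e.beta == pytest.approx(_median_oracle(thetas, 1 / variances), abs=1e-12)


def test_weighted_median_bootstrap_se_is_seeded_and_plausible():
    est = _estimates([0.1, 0.4, 0.2, 0.6, 0.3], [0.2, 0.1, 0.3, 0.2, 0.15])
    a = weighted_median(est, n_boot=2000, seed=5)
    b = weighted_median(est, n_boot=2000, seed=5)
    assert a.se == b.se
    # SE should be in the ballpark of the per-variant uncertainty
    assert 0.05 < a.se < 1.0
    with pytest.raises(ValueError):
        weighted_median(est[:2], n_boot=100, seed=0)


# ------------------------------------------------------------------ MR-Egger

def test_egger_exact_line_through_origin(panel_factory):
    bx = np.array([0.01, 0.02, 0.03, 0.05])
    panel = panel_factory(bx, [0.003] * 4, 0.7 * bx, [0.004, 0.005, 0.006, 0.004])
    e = mr_egger(panel)
    assert e.beta == pytest.approx(0.7, abs=1e-12)
    assert e.egger_intercept == pytest.approx(0.0, abs=1e-12)


def test_egger_exact_affine_fit(panel_factory):
    bx = np.array([0.01, 0.02, 0.03, 0.05, 0.04])
    panel = panel_factory(bx, [0.003] * 5, 0.01 + 0.5 * bx, [0.004] * 5)
    e = mr_egger(panel)
    assert e.beta == pytest.approx(0.5, abs=1e-12)
    assert e.egger_intercept == pytest.approx(0.01, abs=1e-12)


def test_egger_orients_negative_exposure_effects(panel_factory):
    bx = np.array([0.01, -0.02, 0.03, -0.05])
    by = 0.01 + 0.5 * np.abs(bx) + np.array([1, -1, 1, -1]) * 0.0  # on the line after orientation
    by = np.where(bx < 0, -(0.01 + 0.5 * (-bx)), 0.01 + 0.5 * bx)
    panel = panel_factory(bx, [0.003] * 4, by, [0.004] * 4)
    e = mr_egger(panel)
    assert e.beta == pytest.approx(0.5, abs=1e-12)
    assert e.egger_intercept == pytest.approx(0.01, abs=1e-12)


def test_egger_matches_transformed_ols_oracle(random_panel_factory):
    for seed in range(5):
        panel = random_panel_factory(8, seed)
        bx = np.array([abs(v.beta_x) for v in panel.variants])
        by = np.array(
            [v.beta_y if v.beta_x >= 0 else -v.beta_y for v in panel.variants]
        )
        sey = np.array([v.se_y for v in panel.variants])
        # unweighted least squares on 1/se-scaled points == weighted LS
        design = np.column_stack([1 / sey, bx / sey])
        coef, *_ = np.linalg.lstsq(design, by / sey, rcond=None)
        e = mr_egger(panel)
        assert e.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert e.beta == pytest.approx(coef[1], abs=1e-10)


def test_egger_errors(panel_factory):
    with pytest.raises(ValueError, match="three"):
        mr_egger(panel_factory([0.01, 0.02], [0.003] * 2, [0.01, 0.01], [0.004] * 2))
    with pytest.raises(ValueError, match="singular"):
        mr_egger(panel_factory([0.02] * 4, [0.003] * 4, [0.01] * 4, [0.004] * 4))


# ------------------------------------------------------------- OR conversion

def test_odds_ratio_identity_at_zero():
    or_, lo, hi = to_odds_ratio(0.0, 0.1)
    assert or_ == 1.0
    assert lo * hi == pytest.approx(1.0)


@pytest.mark.parametrize(
    "beta, se, expected",
    [
        (-0.342, 0.086, (0.710, 0.600, 0.841)),
        (0.610, 0.0746, (1.840, 1.590, 2.130)),
    ],
)
def test_odds_ratio_closed_form(beta, se, expected):
    or_, lo, hi = to_odds_ratio(beta, se)
    assert or_ == pytest.approx(expected[0], abs=5e-3)
    assert lo == pytest.approx(expected[1], abs=5e-3)
    assert hi == pytest.approx(expected[2], abs=5e-3)
    assert hi == pytest.approx(math.exp(beta + Z95 * se), rel=1e-15)


# --------------------------------------------------------- order equivariance

@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.randoms(use_true_random=False))
def test_estimators_are_order_invariant(rnd):
    rng = np.random.default_rng(rnd.randrange(2**31))
    n = rng.integers(4, 10)
    bx = rng.uniform(0.01, 0.05, n)
    panel_vars = [
        HarmonizedVariant(
            f"rs{i}", bx[i], 0.003, 0.4 * bx[i] + rng.normal(0, 0.01), rng.uniform(0.004, 0.02)
        )
        for i in range(n)
    ]
    from mrdiv import HarmonizedPanel

    p1 = HarmonizedPanel("e", "o", variants=list(panel_vars))
    perm = rng.permutation(n)
    p2 = HarmonizedPanel("e", "o", variants=[panel_vars[i] for i in perm])
    assert ivw(wald_estimates(p1)).beta == pytest.approx(
        ivw(wald_estimates(p2)).beta, rel=1e-12
    )
    assert weighted_median(wald_estimates(p1), n_boot=50, seed=1).beta == pytest.approx(
        weighted_median(wald_estimates(p2), n_boot=50, seed=1).beta, rel=1e-12
    )
    assert mr_egger(p1).beta == pytest.approx(mr_egger(p2).beta, rel=1e-10)
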