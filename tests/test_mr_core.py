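"""MR estimators against closed forms and independent solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrphewas.mr_core import (
    EstimationError,
    InsufficientInstrumentsError,
    MREstimate,
    Z95,
    cochran_q,
    egger,
    ivw,
    max_likelihood,
    to_risk_ratio,
    wald_ratio,
)

from conftest import make_instrument, mr_input_from


def _random_input(seed: int, k: int):
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.2, 0.1, size=k)
    bx[np.abs(bx) < 0.02] = 0.05
    sx = rng.uniform(0.01, 0.05, size=k)
    by = rng.normal(0.1, 0.1, size=k)
    sy = rng.uniform(0.02, 0.1, size=k)
    return mr_input_from(bx, sx, by, sy)


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_arithmetic():
    est = wald_ratio(make_instrument(exposure_beta=0.5, exposure_se=0.1,
                                     outcome_beta=0.25, outcome_se=0.05))
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)
    assert est.ci_low == pytest.approx(0.5 - Z95 * 0.1)
    assert est.nsnp == 1


def test_wald_ratio_null_outcome():
    est = wald_ratio(make_instrument(outcome_beta=0.0))
    assert est.beta == 0.0 and est.pval == pytest.approx(1.0)


def test_wald_ratio_zero_exposure_errors():
    with pytest.raises(EstimationError, match="zero exposure beta"):
        wald_ratio(make_instrument(exposure_beta=0.0))


@pytest.mark.parametrize("seed", range(5))
def test_wald_equals_singleton_ivw(seed):
    rng = np.random.default_rng(seed)
    inst = make_instrument(
        exposure_beta=float(rng.normal(0.3, 0.1)),
        outcome_beta=float(rng.normal(0.1, 0.1)),
        outcome_se=float(rng.uniform(0.01, 0.1)),
    )
    w = wald_ratio(inst)
    i = ivw(mr_input_from([inst.exposure_beta], [inst.exposure_se],
                          [inst.outcome_beta], [inst.outcome_se]))
    assert i.beta == pytest.approx(w.beta, abs=1e-12)
    assert i.se == pytest.approx(w.se, abs=1e-12)


# ---------------------------------------------------------------------------
# IVW


def test_ivw_collinear_instruments_exact():
    mi = mr_input_from([1.0, 2.0, 0.5], [0.1] * 3, [0.4, 0.8, 0.2], [0.1] * 3)
    est = ivw(mi)
    assert est.beta == pytest.approx(0.4, abs=1e-12)
    q = cochran_q(mi)
    assert q.stat == pytest.approx(0.0, abs=1e-12) and q.pval == pytest.approx(1.0)


def test_ivw_identical_instruments_equal_wald():
    inst = make_instrument(exposure_beta=0.4, outcome_beta=0.1)
    mi = mr_input_from([0.4, 0.4], [0.02, 0.02], [0.1, 0.1], [0.02, 0.02])
    assert ivw(mi).beta == pytest.approx(wald_ratio(inst).beta, abs=1e-12)


def test_ivw_degenerate_input_errors():
    with pytest.raises(EstimationError):
        ivw(mr_input_from([0.0, 0.0], [0.1, 0.1], [0.1, 0.2], [0.1, 0.1]))


@pytest.mark.parametrize("seed", range(8))
def test_ivw_closed_form_and_dispersion_rule(seed):
    """IVW slope equals the 1/se^2-weighted mean of Wald ratios; the SE is the
    fixed-effect SE inflated (never deflated) by residual dispersion."""
    mi = _random_input(seed, k=6)
    bx, _, by, sy = mi.arrays()
    est = ivw(mi)
    w = (bx / sy) ** 2
    assert est.beta == pytest.approx(np.sum(w * by / bx) / np.sum(w), abs=1e-10)
    se_fixed = 1 / np.sqrt(np.sum(bx**2 / sy**2))
    resid = by - est.beta * bx
    sigma = np.sqrt(np.sum(resid**2 / sy**2) / (len(bx) - 1))
    assert est.se == pytest.approx(se_fixed * max(sigma, 1.0), abs=1e-12)
    assert est.se >= se_fixed - 1e-15


@pytest.mark.parametrize("seed", range(4))
def test_ivw_matches_statsmodels_wls(seed):
    import statsmodels.api as sm

    mi = _random_input(seed + 50, k=8)
    bx, _, by, sy = mi.arrays()
    fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
    est = ivw(mi)
    assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-10)
    sigma = np.sqrt(fit.scale)
    expected_se = float(fit.bse[0]) / min(sigma, 1.0)
    assert est.se == pytest.approx(expected_se, abs=1e-10)


def test_ivw_recovers_simulated_effect():
    from mrphewas.gwas_data import harmonise_pair, select_instruments
    from mrphewas.ld_reference import clump
    from mrphewas.mr_core import MRInput
    from mrphewas.synthetic_data import SimulationConfig, simulate_two_sample

    cfg = SimulationConfig(seed=101, theta=0.4, m_snps=120, n_causal_instruments=100,
                           n_outcome_snps=10)
    ds = simulate_two_sample(cfg)
    out = {o.variant_id: o for o in ds.outcome}
    sel = clump(select_instruments(ds.exposure), ds.panel)
    kept = [h for h in (harmonise_pair(a, out[a.variant_id]) for a in sel) if h.usable]
    est = ivw(MRInput(ds.exposure_trait, ds.outcome_trait, kept))
    assert abs(est.beta - 0.4) < 3 * est.se


# ---------------------------------------------------------------------------
# Egger


def test_egger_on_origin_line_zero_intercept():
    mi = mr_input_from([1.0, 2.0, 0.5, 1.5], [0.1] * 4,
                       [0.4, 0.8, 0.2, 0.6], [0.1] * 4)
    res = egger(mi)
    assert abs(res.intercept) < 1e-10
    assert res.slope.beta == pytest.approx(0.4, abs=1e-10)


def test_egger_constant_shift_moves_intercept_only():
    mi = _random_input(3, k=6)
    bx, sx, by, sy = mi.arrays()
    base = egger(mi)
    shifted = egger(mr_input_from(bx, sx, by + 0.25, sy))
    assert shifted.intercept == pytest.approx(base.intercept + 0.25, abs=1e-10)
    assert shifted.slope.beta == pytest.approx(base.slope.beta, abs=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_egger_matches_wls_oracle(seed):
    import statsmodels.api as sm

    mi = _random_input(seed + 20, k=7)
    bx, _, by, sy = mi.arrays()
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1 / sy**2).fit()
    res = egger(mi)
    assert res.intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
    assert res.slope.beta == pytest.approx(float(fit.params[1]), abs=1e-10)
    scale = max(np.sqrt(fit.scale), 1.0)
    unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    assert res.intercept_se == pytest.approx(float(unscaled[0]) * scale, abs=1e-10)
    assert res.slope.se == pytest.approx(float(unscaled[1]) * scale, abs=1e-10)


def test_egger_needs_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger(_random_input(0, k=2))


# ---------------------------------------------------------------------------
# Maximum likelihood


def test_ml_identical_ratios_exact():
    mi = mr_input_from([0.2, 0.4, 0.3], [0.02] * 3, [0.1, 0.2, 0.15], [0.02] * 3)
    est, het = max_likelihood(mi)
    assert est.beta == pytest.approx(0.5, abs=1e-6)
    assert het.stat < 1e-6 and het.pval == pytest.approx(1.0, abs=1e-6)
    assert het.df == 2


@pytest.mark.parametrize("seed", range(5))
def test_ml_matches_grid_search(seed):
    mi = _random_input(seed + 30, k=3)
    bx, sx, by, sy = mi.arrays()
    grid = np.linspace(-3, 3, 600001)
    v = sy[None, :] ** 2 + grid[:, None] ** 2 * sx[None, :] ** 2
    rss = np.sum((by[None, :] - grid[:, None] * bx[None, :]) ** 2 / v, axis=1)
    theta_grid = grid[np.argmin(rss)]
    est, _ = max_likelihood(mi)
    assert est.beta == pytest.approx(theta_grid, abs=1e-4)


def test_ml_close_to_ivw_with_strong_homogeneous_instruments():
    rng = np.random.default_rng(17)
    k = 100
    bx = rng.uniform(0.1, 0.3, size=k)
    sx = np.full(k, 0.005)
    sy = np.full(k, 0.01)
    by = 0.4 * bx + rng.normal(0, 0.01, size=k)
    mi = mr_input_from(bx, sx, by, sy)
    est_ml, _ = max_likelihood(mi)
    est_ivw = ivw(mi)
    assert est_ml.beta == pytest.approx(est_ivw.beta, rel=0.02)


def test_ml_requires_two_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        max_likelihood(mr_input_from([0.2], [0.02], [0.1], [0.02]))


# ---------------------------------------------------------------------------
# Cochran's Q


def test_cochran_q_hand_example():
    # ratios 0.4 and 0.6 with weights (bx/sy)^2 = 100 each -> Q = 2.0
    mi = mr_input_from([1.0, 1.0], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])
    q = cochran_q(mi)
    assert q.stat == pytest.approx(2.0, abs=1e-12)
    assert q.df == 1
    assert q.pval == pytest.approx(float(stats.chi2.sf(2.0, 1)), abs=1e-12)


@pytest.mark.parametrize("k", [2, 5, 9])
def test_cochran_df_is_nsnp_minus_one(k):
    assert cochran_q(_random_input(k, k=k)).df == k - 1


# ---------------------------------------------------------------------------
# Shared invariants


@pytest.mark.parametrize("seed", range(4))
def test_sign_equivariance(seed):
    mi = _random_input(seed + 70, k=6)
    bx, sx, by, sy = mi.arrays()
    neg_x = mr_input_from(-bx, sx, by, sy)
    both = mr_input_from(-bx, sx, -by, sy)
    assert ivw(neg_x).beta == pytest.approx(-ivw(mi).beta, abs=1e-12)
    assert ivw(both).beta == pytest.approx(ivw(mi).beta, abs=1e-12)
    ml, _ = max_likelihood(mi)
    ml_neg, _ = max_likelihood(neg_x)
    ml_both, _ = max_likelihood(both)
    assert ml_neg.beta == pytest.approx(-ml.beta, abs=1e-6)
    assert ml_both.beta == pytest.approx(ml.beta, abs=1e-6)
    assert egger(neg_x).slope.beta == pytest.approx(-egger(mi).slope.beta, abs=1e-12)


def test_estimate_invariants():
    est = MREstimate.from_beta_se("ivw", 0.3, 0.1, nsnp=5)
    assert est.ci_low == pytest.approx(0.3 - 1.959964 * 0.1)
    assert est.ci_high == pytest.approx(0.3 + 1.959964 * 0.1)
    assert est.pval == pytest.approx(float(2 * stats.norm.sf(3.0)))


def test_to_risk_ratio_matches_reported_conversions():
    rr, lo, hi = to_risk_ratio(MREstimate.from_beta_se("ivw", 2.39, 0.26, 6))
    assert round(rr, 2) == 10.91
    rr_bmi, _, _ = to_risk_ratio(MREstimate.from_beta_se("ivw", 0.40, 0.04, 305))
    assert round(rr_bmi, 2) == 1.49
    assert to_risk_ratio(MREstimate.from_beta_se("ivw", 0.0, 0.1, 1))[0] == 1.0
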