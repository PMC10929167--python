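"""Univariable estimators: worked examples, oracles, and shared invariants."""

import numpy as np
import pytest

from mrscreen.errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ValidationError,
)
from mrscreen.estimators import (
    EstimatorConfig,
    egger,
    ivw,
    maximum_likelihood,
    ml_profile_loglik,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_harmonized, random_harmonized


class TestWaldRatio:
    def test_direct_formula(self):
        est = wald_ratio(0.1, 0.02, 0.05, 0.03)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.3)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.02, 0.0, 0.03).beta == 0.0

    def test_scale_equivariance(self):
        base = wald_ratio(0.1, 0.02, 0.05, 0.03)
        scaled = wald_ratio(0.2, 0.04, 0.05, 0.03)
        assert scaled.beta == pytest.approx(base.beta / 2)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.02, 0.05, 0.03)

    def test_second_order_se_is_larger(self):
        first = wald_ratio(0.1, 0.02, 0.05, 0.03)
        second = wald_ratio(0.1, 0.02, 0.05, 0.03, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_single_instrument_reduces_to_wald(self, fast_cfg):
        h = make_harmonized([0.1], [0.02], [0.05], [0.03])
        est = ivw(h, fast_cfg)
        wald = wald_ratio(0.1, 0.02, 0.05, 0.03)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_three_instrument_worked_example(self, three_snp_set, fast_cfg):
        est = ivw(three_snp_set, fast_cfg)
        assert est.beta == pytest.approx(0.5258, abs=1e-4)
        assert est.se == pytest.approx(0.2120, abs=1e-4)

    def test_homogeneous_ratios_exact(self, fast_cfg):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3,
                            [0.07, 0.14, 0.21], [0.05] * 3)
        assert ivw(h, fast_cfg).beta == pytest.approx(0.7, abs=1e-12)

    def test_fixed_se_never_exceeds_random_se(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            h = random_harmonized(rng, J=int(rng.integers(2, 15)))
            se_f = ivw(h, EstimatorConfig(ivw_mode="fixed")).se
            se_r = ivw(h, EstimatorConfig(ivw_mode="multiplicative_random")).se
            assert se_f <= se_r + 1e-15

    def test_matches_generic_wls_oracle(self, fast_cfg):
        rng = np.random.default_rng(17)
        for _ in range(20):
            h = random_harmonized(rng, J=8)
            w = 1.0 / h.se_out**2
            coef, *_ = np.linalg.lstsq(
                (np.sqrt(w) * h.beta_exp)[:, None], np.sqrt(w) * h.beta_out,
                rcond=None,
            )
            assert ivw(h, fast_cfg).beta == pytest.approx(coef[0], abs=1e-10)


class TestMaximumLikelihood:
    def test_negligible_exposure_noise_matches_ivw(self, fast_cfg):
        rng = np.random.default_rng(2)
        h = random_harmonized(rng, J=12)
        h.se_exp = np.full_like(h.se_exp, 1e-8)
        ml = maximum_likelihood(h, fast_cfg)
        assert ml.beta == pytest.approx(ivw(h, fast_cfg).beta, abs=1e-4)

    def test_likelihood_at_optimum_beats_ivw_start(self, fast_cfg):
        rng = np.random.default_rng(8)
        for _ in range(10):
            h = random_harmonized(rng, J=10, theta=-1.0)
            ml = maximum_likelihood(h, fast_cfg)
            assert ml_profile_loglik(h, ml.beta) >= ml_profile_loglik(
                h, ivw(h, fast_cfg).beta) - 1e-9

    def test_null_coverage_on_simulated_data(self):
        from mrscreen.simulate import SimConfig, simulate_pair

        inside = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = SimConfig(n_taxa=1, instruments_per_taxon=50, theta=0.0,
                            seed=20_000 + rep)
            exps, out, _, _ = simulate_pair(cfg)
            df = exps["taxon_1"]
            h = make_harmonized(df["beta"], df["se"], out["beta"], out["se"])
            ml = maximum_likelihood(h)
            inside += abs(ml.beta) < 3 * ml.se
        assert inside >= 0.97 * n_rep


class TestEgger:
    def test_exact_linear_recovery(self, fast_cfg):
        bx = np.array([0.1, 0.15, 0.2, 0.3, 0.25])
        by = 0.04 + (-1.2) * bx
        h = make_harmonized(bx, [0.01] * 5, by, [0.05] * 5)
        slope, intercept = egger(h, fast_cfg)
        assert slope.beta == pytest.approx(-1.2, abs=1e-12)
        assert intercept["estimate"] == pytest.approx(0.04, abs=1e-12)

    def test_null_pleiotropy_recovers_ratio(self, fast_cfg):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        h = make_harmonized(bx, [0.01] * 4, 0.6 * bx, [0.05] * 4)
        slope, intercept = egger(h, fast_cfg)
        assert slope.beta == pytest.approx(0.6, abs=1e-10)
        assert intercept["estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_generic_weighted_regression_oracle(self, fast_cfg):
        rng = np.random.default_rng(23)
        h = random_harmonized(rng, J=10)
        flip = np.where(h.beta_exp < 0, -1.0, 1.0)
        bx, by = h.beta_exp * flip, h.beta_out * flip
        w = 1.0 / h.se_out**2
        X = np.column_stack([np.ones_like(bx), bx])
        Xw = np.sqrt(w)[:, None] * X
        coef, *_ = np.linalg.lstsq(Xw, np.sqrt(w) * by, rcond=None)
        resid = by - X @ coef
        s2 = np.sum(w * resid**2) / (len(bx) - 2)
        cov = s2 * np.linalg.inv(Xw.T @ Xw)
        slope, intercept = egger(h, fast_cfg)
        assert slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert intercept["estimate"] == pytest.approx(coef[0], abs=1e-10)
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)
        assert intercept["se"] == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)

    def test_too_few_instruments(self, fast_cfg):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h, fast_cfg)


class TestWeightedMedian:
    def test_equal_weights_simple_median(self, fast_cfg):
        h = make_harmonized([0.1] * 3, [0.01] * 3,
                            [0.01, 0.05, 0.09], [0.05] * 3)
        assert weighted_median(h, fast_cfg).beta == pytest.approx(0.5)

    def test_weight_shift_moves_estimate_up(self, fast_cfg):
        # ratios (0.1, 0.5, 0.9), weights proportional to (1, 1, 6):
        # interpolated estimate 0.7857 by the hand-evaluated formula
        bx = np.array([0.1, 0.1, 0.1 * np.sqrt(6)])
        by = np.array([0.1, 0.5, 0.9]) * bx
        h = make_harmonized(bx, [0.01] * 3, by, [0.05] * 3)
        est = weighted_median(h, fast_cfg).beta
        assert est == pytest.approx(0.785714, abs=1e-6)
        assert 0.5 < est <= 0.9

    def test_seeding_contract(self):
        rng = np.random.default_rng(31)
        h = random_harmonized(rng, J=8)
        cfg_a = EstimatorConfig(n_boot=1000, seed=42)
        cfg_b = EstimatorConfig(n_boot=1000, seed=43)
        se_a1 = weighted_median(h, cfg_a).se
        se_a2 = weighted_median(h, cfg_a).se
        se_b = weighted_median(h, cfg_b).se
        assert se_a1 == se_a2
        assert se_b == pytest.approx(se_a1, rel=0.10)

    def test_too_few_instruments(self, fast_cfg):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h, fast_cfg)


class TestWeightedMode:
    def test_degenerate_cluster_returns_common_ratio(self, fast_cfg):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, [0.01] * 3, -1.5 * bx, [0.05] * 3)
        assert weighted_mode(h, fast_cfg).beta == pytest.approx(-1.5)

    def test_majority_cluster_wins(self, fast_cfg):
        ratios = np.array([-2.1, -2.0, -1.95, -2.05, -1.9, -2.02, -1.98,
                           1.0, 0.95, 1.05])
        bx = np.full(10, 0.2)
        h = make_harmonized(bx, [0.01] * 10, ratios * bx, [0.05] * 10)
        est = weighted_mode(h, fast_cfg).beta
        assert est == pytest.approx(-2.0, abs=0.15)

    def test_bandwidth_factor_stable_for_separated_clusters(self, fast_cfg):
        # nine-point tight cluster keeps the IQR (hence bandwidth) tiny, so
        # the clusters stay many bandwidths apart at both phi values
        ratios = np.array([-2.0, -2.001, -2.002, -1.999, -1.998,
                           -2.0005, -1.9995, -2.0015, -1.9985, 1.0, 1.001])
        bx = np.full(11, 0.2)
        h = make_harmonized(bx, [0.01] * 11, ratios * bx, [0.05] * 11)
        est1 = weighted_mode(h, EstimatorConfig(n_boot=100, seed=1,
                                                mode_bandwidth_factor=1.0)).beta
        est2 = weighted_mode(h, EstimatorConfig(n_boot=100, seed=1,
                                                mode_bandwidth_factor=2.0)).beta
        assert est1 == pytest.approx(est2, abs=0.05)


ALL = {
    "ivw": ivw,
    "ml": maximum_likelihood,
    "egger": lambda h, c: egger(h, c)[0],
    "median": weighted_median,
    "mode": weighted_mode,
}


@pytest.mark.parametrize("name", list(ALL))
def test_sign_antisymmetry_in_outcome(name, fast_cfg):
    """Negating every outcome effect negates the causal estimate, SE unchanged."""
    rng = np.random.default_rng(11)
    h = random_harmonized(rng, J=10, theta=0.8)
    neg = make_harmonized(h.beta_exp, h.se_exp, -h.beta_out, h.se_out)
    if name in ("median", "mode"):
        # bootstrap SEs share the seed but not mirrored draws: MC slack
        cfg, tol = EstimatorConfig(ivw_mode="fixed", n_boot=1000, seed=7), 0.15
    else:
        cfg, tol = fast_cfg, 1e-5
    a = ALL[name](h, cfg)
    b = ALL[name](neg, cfg)
    assert b.beta == pytest.approx(-a.beta, abs=1e-6)
    assert b.se == pytest.approx(a.se, rel=tol)


@pytest.mark.parametrize("name", list(ALL))
def test_scale_equivariance_in_exposure(name, fast_cfg):
    """Scaling (beta_exp, se_exp) by c scales the estimate by 1/c."""
    rng = np.random.default_rng(13)
    h = random_harmonized(rng, J=10, theta=-0.6)
    c = 2.5
    scaled = make_harmonized(c * h.beta_exp, c * h.se_exp, h.beta_out, h.se_out)
    a = ALL[name](h, fast_cfg)
    b = ALL[name](scaled, fast_cfg)
    assert b.beta == pytest.approx(a.beta / c, abs=1e-6)


def test_config_invariants():
    with pytest.raises(ValidationError):
        EstimatorConfig(n_boot=50)
    with pytest.raises(ValidationError):
        EstimatorConfig(ivw_mode="nope")
    with pytest.raises(ValidationError):
        EstimatorConfig(mode_bandwidth_factor=0.0)
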