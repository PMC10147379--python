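import math
from dataclasses import replace

import numpy as np
import pytest

from tsmr.estimators import (
    i2_gx,
    ivw,
    mr_egger,
    simex_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from tsmr.harmonize import harmonize
from tsmr.simulate import SimConfig, scenario_preset, simulate_two_sample

from conftest import flipped_set, hset_from_arrays


# ---------------------------------------------------------------- oracles

def ivw_oracle(bx, bxse, by, byse):
    """Closed-form weighted regression through the origin, scalar arithmetic."""
    w = [1.0 / s**2 for s in byse]
    num = math.fsum(wi * x * y for wi, x, y in zip(w, bx, by))
    den = math.fsum(wi * x * x for wi, x in zip(w, bx))
    beta = num / den
    se_fe = math.sqrt(1.0 / den)
    k = len(bx)
    phi = math.fsum(wi * (y - beta * x) ** 2 for wi, x, y in zip(w, bx, by)) / (k - 1)
    return beta, se_fe, se_fe * math.sqrt(max(1.0, phi))

def egger_oracle(bx, by, byse):
    """Weighted regression with intercept via statsmodels, oriented bx >= 0."""
    import statsmodels.api as sm

    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    byse = np.asarray(byse, float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / byse**2).fit()
    scale = res.scale
    floor = math.sqrt(max(1.0, scale) / scale)
    return (
        res.params[1], res.params[0],
        res.bse[1] * floor, res.bse[0] * floor,
    )

def median_oracle(ratios, weights):
    """Scan the piecewise-linear weighted CDF on a fine grid for its 0.5 point."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    p = np.cumsum(w) - 0.5 * w
    xs = np.linspace(r[0], r[-1], 1_000_001)
    cdf = np.interp(xs, r, p)
    return float(xs[np.argmin(np.abs(cdf - 0.5))])

def mode_oracle(ratios, weights, phi=1.0):
    """Dense-grid argmax of the weighted normal-kernel density."""
    r = np.asarray(ratios, float)
    w = np.asarray(weights, float) / np.sum(weights)
    k = r.size
    sd = np.std(r, ddof=1)
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    h = phi * 0.9 * min(sd, iqr / 1.349) * k ** (-0.2)

    def dens(xs):
        z = (xs[:, None] - r[None, :]) / h
        return (w[None, :] * np.exp(-0.5 * z * z)).sum(axis=1)

    xs = np.linspace(r.min() - 2 * h, r.max() + 2 * h, 100_001)
    x0 = xs[np.argmax(dens(xs))]
    step = xs[1] - xs[0]
    xs2 = np.linspace(x0 - 2 * step, x0 + 2 * step, 100_001)
    return float(xs2[np.argmax(dens(xs2))])


def _ratio_weights(bx, byse):
    w = np.asarray(bx) ** 2 / np.asarray(byse) ** 2
    return w / w.sum()


# ---------------------------------------------------------------- Wald

class TestWaldRatio:
    def test_first_order_closed_form(self, small_hset):
        r = replace(small_hset.records[0], beta_exp=0.1, beta_out=0.05, se_out=0.02)
        e = wald_ratio(r)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)

    def test_zero_outcome_beta(self, small_hset):
        r = replace(small_hset.records[0], beta_out=0.0)
        assert wald_ratio(r).beta == 0.0

    def test_second_order_reduces_to_first_with_zero_se_exp(self, small_hset):
        r = replace(small_hset.records[0], se_exp=0.0)
        assert wald_ratio(r, "second_order").se == pytest.approx(wald_ratio(r).se)

    def test_second_order_larger(self, small_hset):
        r = small_hset.records[0]
        assert wald_ratio(r, "second_order").se > wald_ratio(r, "first_order").se

    def test_zero_exposure_beta_is_error(self, small_hset):
        r = replace(small_hset.records[0], beta_exp=0.0)
        with pytest.raises(ValueError):
            wald_ratio(r)


# ---------------------------------------------------------------- IVW

class TestIVW:
    def test_identical_ratios_exact(self):
        h = hset_from_arrays([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.02, 0.02])
        assert ivw(h).beta == pytest.approx(0.5, abs=1e-15)

    def test_single_snp_equals_wald(self):
        h = hset_from_arrays([0.1], [0.01], [0.04], [0.02])
        e = ivw(h)
        w = wald_ratio(h.records[0], scale=h.scale)
        assert e.beta == w.beta and e.se == w.se and e.pval == w.pval
        assert e.method == "ivw"

    def test_matches_closed_form_oracle(self, small_hset):
        bx, bxse, by, byse = small_hset.arrays()
        beta_o, se_fe_o, se_mre_o = ivw_oracle(bx, bxse, by, byse)
        e = ivw(small_hset)
        ef = ivw(small_hset, model="fixed_effects")
        assert e.beta == pytest.approx(beta_o, abs=1e-10)
        assert ef.se == pytest.approx(se_fe_o, abs=1e-10)
        assert e.se == pytest.approx(se_mre_o, abs=1e-10)

    def test_se_out_scaling_property(self, small_hset):
        c = 3.0
        bx, bxse, by, byse = small_hset.arrays()
        scaled = hset_from_arrays(bx, bxse, by, byse * c)
        e1 = ivw(small_hset, model="fixed_effects")
        e2 = ivw(scaled, model="fixed_effects")
        assert e2.beta == pytest.approx(e1.beta, abs=1e-12)
        assert e2.se == pytest.approx(c * e1.se, rel=1e-12)

    def test_mre_se_at_least_fixed(self, small_hset):
        assert ivw(small_hset).se >= ivw(small_hset, model="fixed_effects").se

    def test_all_zero_exposure_error(self):
        h = hset_from_arrays([0.0, 0.0], [0.01, 0.01], [0.1, 0.2], [0.02, 0.02])
        with pytest.raises(ValueError):
            ivw(h)

    def test_ci_brackets_beta(self, small_hset):
        e = ivw(small_hset)
        assert e.ci_low <= e.beta <= e.ci_high


# ---------------------------------------------------------------- Egger

class TestMREgger:
    def test_noiseless_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        by = 0.02 + 0.3 * bx
        h = hset_from_arrays(bx, np.zeros(5), by, np.ones(5))
        r = mr_egger(h)
        assert r.slope.beta == pytest.approx(0.3, abs=1e-12)
        assert r.intercept.beta == pytest.approx(0.02, abs=1e-12)

    def test_affine_shift_moves_intercept_only(self, small_hset):
        r1 = mr_egger(small_hset)
        bx, bxse, by, byse = small_hset.arrays()
        shifted = hset_from_arrays(bx, bxse, by + 0.01, byse)
        r2 = mr_egger(shifted)
        assert r2.slope.beta == pytest.approx(r1.slope.beta, abs=1e-12)
        assert r2.intercept.beta == pytest.approx(r1.intercept.beta + 0.01, abs=1e-12)

    def test_matches_wls_oracle(self, small_hset):
        bx, bxse, by, byse = small_hset.arrays()
        slope_o, int_o, se_s_o, se_i_o = egger_oracle(bx, by, byse)
        r = mr_egger(small_hset)
        assert r.slope.beta == pytest.approx(slope_o, abs=1e-10)
        assert r.intercept.beta == pytest.approx(int_o, abs=1e-10)
        assert r.slope.se == pytest.approx(se_s_o, abs=1e-10)
        assert r.intercept.se == pytest.approx(se_i_o, abs=1e-10)

    def test_too_few_snps(self):
        h = hset_from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError):
            mr_egger(h)

    def test_collinear_exposure_error(self):
        h = hset_from_arrays([0.1, 0.1, -0.1], [0.01] * 3, [0.05, 0.06, 0.04], [0.02] * 3)
        with pytest.raises(ValueError, match="collinear"):
            mr_egger(h)


# ---------------------------------------------------------------- median

class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        h = hset_from_arrays([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9], [0.1] * 3)
        assert weighted_median(h, n_boot=0).beta == pytest.approx(0.5)

    def test_dominant_snp(self):
        # first SNP carries >50% of the weight; its ratio wins
        h = hset_from_arrays(
            [1.0, 0.1, 0.1], [0.01] * 3, [0.7, 0.01, 0.09], [0.05, 0.05, 0.05]
        )
        w = _ratio_weights([1.0, 0.1, 0.1], [0.05] * 3)
        assert w[0] > 0.5
        assert weighted_median(h, n_boot=0).beta == pytest.approx(0.7, abs=1e-9)

    def test_seven_snp_grid_oracle(self, rng):
        bx = rng.uniform(0.05, 0.3, 7)
        byse = rng.uniform(0.01, 0.05, 7)
        by = 0.25 * bx + rng.normal(0, 0.02, 7)
        h = hset_from_arrays(bx, np.zeros(7), by, byse)
        expected = median_oracle(by / bx, _ratio_weights(bx, byse))
        assert weighted_median(h, n_boot=0).beta == pytest.approx(expected, abs=1e-6)

    def test_bootstrap_reproducible_and_warns(self, small_hset):
        with pytest.warns(UserWarning, match="n_boot"):
            e1 = weighted_median(small_hset, n_boot=50, seed=9)
        with pytest.warns(UserWarning, match="n_boot"):
            e2 = weighted_median(small_hset, n_boot=50, seed=9)
        assert e1.se == e2.se and e1.se > 0

    def test_between_min_and_max_ratio(self, small_hset):
        bx, _, by, _ = small_hset.arrays()
        ratios = by / bx
        e = weighted_median(small_hset, n_boot=0)
        assert ratios.min() <= e.beta <= ratios.max()


# ---------------------------------------------------------------- mode

class TestWeightedMode:
    def test_majority_cluster(self):
        h = hset_from_arrays(
            [1.0, 1.0, 1.0, 1.0], [0.01] * 4, [0.5, 0.5, 0.5, 2.0], [0.1] * 4
        )
        assert weighted_mode(h, n_boot=0).beta == pytest.approx(0.5, abs=0.05)

    def test_phi_stability_on_tight_cluster(self, rng):
        bx = np.ones(8)
        by = 0.4 + rng.normal(0, 0.005, 8)
        h = hset_from_arrays(bx, np.zeros(8), by, np.full(8, 0.05))
        m1 = weighted_mode(h, phi=1.0, n_boot=0).beta
        m2 = weighted_mode(h, phi=0.5, n_boot=0).beta
        assert m1 == pytest.approx(m2, abs=0.02)

    def test_nine_snp_bimodal_grid_oracle(self, rng):
        ratios = np.array([0.1, 0.12, 0.11, 0.13, 0.09, 0.5, 0.52, 0.51, 0.115])
        bx = rng.uniform(0.1, 0.3, 9)
        byse = rng.uniform(0.01, 0.03, 9)
        by = ratios * bx
        h = hset_from_arrays(bx, np.zeros(9), by, byse)
        expected = mode_oracle(by / bx, _ratio_weights(bx, byse))
        assert weighted_mode(h, n_boot=0).beta == pytest.approx(expected, abs=1e-6)

    def test_bootstrap_reproducible(self, small_hset):
        e1 = weighted_mode(small_hset, n_boot=120, seed=4)
        e2 = weighted_mode(small_hset, n_boot=120, seed=4)
        assert e1.se == e2.se and e1.se > 0


# ---------------------------------------------------------------- I2 / SIMEX

class TestI2GX:
    def test_equal_betas_zero(self):
        h = hset_from_arrays([0.1] * 4, [0.01] * 4, [0.1] * 4, [0.02] * 4)
        assert i2_gx(h) == 0.0

    def test_tiny_se_limit_one(self):
        h = hset_from_arrays([0.1, 0.2, 0.3], [1e-8] * 3, [0.1] * 3, [0.02] * 3)
        assert i2_gx(h) > 0.999999

    def test_monte_carlo_matches_f_limit(self):
        # mean per-SNP F ~ 30 -> I2 ~ (30 - 1)/30 over 200 seeded reps
        vals = []
        for seed in range(200):
            cfg = SimConfig(n_snps=100, n_exposure_sample=100_000, r2_target=0.029, seed=seed)
            exposure, outcome, _, _ = simulate_two_sample(cfg)
            vals.append(i2_gx(harmonize(exposure, outcome)))
        assert abs(np.mean(vals) - 29 / 30) < 0.02


class TestSimexEgger:
    def test_zero_measurement_error_equals_egger(self, small_hset):
        bx, _, by, byse = small_hset.arrays()
        h = hset_from_arrays(bx, np.zeros(len(bx)), by, byse)
        base = mr_egger(h)
        sx = simex_egger(h, seed=1)
        assert sx.slope.beta == base.slope.beta
        assert sx.slope.se == base.slope.se
        assert sx.slope.method == "egger_simex"

    def test_lambda_zero_only_equals_egger(self, small_hset):
        base = mr_egger(small_hset)
        sx = simex_egger(small_hset, lambdas=(0.0,), seed=1)
        assert sx.slope.beta == base.slope.beta
        assert sx.intercept.beta == base.intercept.beta

    def test_reproducible(self, small_hset):
        a = simex_egger(small_hset, n_sim=50, seed=7)
        b = simex_egger(small_hset, n_sim=50, seed=7)
        assert a.slope.beta == b.slope.beta

    def test_corrects_attenuation_under_weak_instruments(self):
        # I2 ~ 0.6 regime with true slope 0.3: SIMEX beats naive Egger
        wins = 0
        i2s = []
        for seed in range(100):
            cfg = SimConfig(
                n_snps=50, n_exposure_sample=50_000, r2_target=0.0015,
                causal_beta=0.3, outcome_type="continuous",
                n_outcome_cases=2_500_000, n_outcome_controls=2_500_000, seed=seed,
            )
            exposure, outcome, _, _ = simulate_two_sample(cfg)
            h = harmonize(exposure, outcome)
            i2s.append(i2_gx(h))
            naive = mr_egger(h)
            sx = simex_egger(h, n_sim=40, seed=seed)
            wins += abs(sx.slope.beta - 0.3) < abs(naive.slope.beta - 0.3)
        assert 0.4 < np.mean(i2s) < 0.8
        assert wins >= 80

    def test_unknown_extrapolation(self, small_hset):
        with pytest.raises(ValueError):
            simex_egger(small_hset, extrapolation="cubic")


# ---------------------------------------------------------------- invariants

class TestOrientationInvariance:
    def test_all_estimators_invariant_to_record_flips(self, small_hset):
        flipped = flipped_set(small_hset, {0, 2, 4})
        assert ivw(flipped).beta == pytest.approx(ivw(small_hset).beta, abs=1e-15)
        assert ivw(flipped).se == pytest.approx(ivw(small_hset).se, abs=1e-15)
        e1, e2 = mr_egger(small_hset), mr_egger(flipped)
        assert e2.slope.beta == e1.slope.beta
        assert e2.intercept.beta == e1.intercept.beta
        m1 = weighted_median(small_hset, n_boot=200, seed=3)
        m2 = weighted_median(flipped, n_boot=200, seed=3)
        assert m2.beta == m1.beta and m2.se == m1.se  # bit-identical
        o1 = weighted_mode(small_hset, n_boot=0)
        o2 = weighted_mode(flipped, n_boot=0)
        assert o2.beta == o1.beta


class TestBalancedPleiotropyContract:
    def test_egger_intercept_centred_under_inside(self):
        # 100% balanced pleiotropy satisfying InSIDE: intercept mean ~ 0
        ints = []
        for seed in range(500):
            exposure, outcome, _, _ = simulate_two_sample(scenario_preset("balanced", seed=seed))
            ints.append(mr_egger(harmonize(exposure, outcome)).intercept.beta)
        assert abs(np.mean(ints)) < 0.002
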