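import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtriad.estimators import (
    _mode_point,
    _weighted_median_point,
    all_estimates,
    egger,
    ivw,
    kernel_density,
    mode_estimate,
    ratio_estimates,
    to_odds_ratio,
    wald_single,
    weighted_median,
)
from mrtriad.instruments import HarmonizedSet

from conftest import make_harmonized


class TestRatioEstimates:
    def test_hand_arithmetic_single(self):
        h = make_harmonized([0.1], [0.02], beta_exp=[0.5])
        r = ratio_estimates(h)
        # beta_out = 0.05, se_out = 0.01, beta_exp = 0.5
        assert r["wald"].iloc[0] == pytest.approx(0.1)
        assert r["wald_se"].iloc[0] == pytest.approx(0.02)

    def test_zero_outcome_beta(self):
        h = make_harmonized([0.0], [0.02])
        assert ratio_estimates(h)["wald"].iloc[0] == 0.0

    def test_three_snp_hand_computation(self):
        # beta_exp = [0.5, 0.25, -0.2], beta_out = [0.05, 0.05, 0.04]
        # ratios = [0.1, 0.2, -0.2]; ses = se_out/|beta_exp|
        import pandas as pd

        t = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "beta_exp": [0.5, 0.25, -0.2],
                "se_exp": [0.01] * 3,
                "beta_out": [0.05, 0.05, 0.04],
                "se_out": [0.01, 0.02, 0.01],
                "f_stat": [2500.0, 625.0, 400.0],
                "flipped": [False] * 3,
            }
        )
        r = ratio_estimates(HarmonizedSet("e", "o", t))
        np.testing.assert_allclose(r["wald"], [0.1, 0.2, -0.2])
        np.testing.assert_allclose(r["wald_se"], [0.02, 0.08, 0.05])

    def test_zero_beta_exp_dropped(self):
        import pandas as pd

        t = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "beta_exp": [1.0, 0.0],
                "se_exp": [0.01, 0.01],
                "beta_out": [0.1, 0.2],
                "se_out": [0.02, 0.02],
                "f_stat": [10000.0, 0.0],
                "flipped": [False, False],
            }
        )
        r = ratio_estimates(HarmonizedSet("e", "o", t))
        assert len(r) == 1
        assert r.attrs["n_dropped"] == 1


class TestIVW:
    def test_degenerate_agreement(self):
        h = make_harmonized([0.1, 0.1], [0.02, 0.03])
        e = ivw(h)
        assert e.beta == pytest.approx(0.1)
        # Q = 0 so random-effects inflation floors at the fixed-effect se
        w = 1 / 0.02**2 + 1 / 0.03**2
        assert e.se == pytest.approx(np.sqrt(1 / w))

    def test_fewer_than_two_snps_is_error(self):
        h = make_harmonized([0.1], [0.02])
        with pytest.raises(ValueError):
            ivw(h)
        assert wald_single(h).beta == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_zero_intercept_wls_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n = 20
        bx = gen.uniform(0.05, 0.3, n)
        by = 0.2 * bx + gen.normal(0, 0.01, n)
        se_out = gen.uniform(0.005, 0.03, n)
        h = make_harmonized(by / bx, se_out / bx, beta_exp=bx)
        fit = sm.WLS(by, bx, weights=1 / se_out**2).fit()
        assert ivw(h).beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_fixed_vs_random_effects_inflation(self, small_harmonized):
        from mrtriad.sensitivity import cochran_q

        e_re = ivw(small_harmonized, random_effects=True)
        e_fe = ivw(small_harmonized, random_effects=False)
        q = cochran_q(small_harmonized)
        expected = max(1.0, q["q_stat"] / q["q_df"])
        assert (e_re.se / e_fe.se) ** 2 == pytest.approx(expected, rel=1e-9)

    def test_ci_convention(self, small_harmonized):
        e = ivw(small_harmonized)
        assert e.ci_low == pytest.approx(e.beta - 1.96 * e.se)
        assert e.ci_high == pytest.approx(e.beta + 1.96 * e.se)


class TestEgger:
    def test_exact_line_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        a_true, b_true = 0.02, 0.3
        by = a_true + b_true * bx
        h = make_harmonized(by / bx, 0.01 / bx, beta_exp=bx)
        e = egger(h)
        assert e.intercept == pytest.approx(a_true, abs=1e-10)
        assert e.beta == pytest.approx(b_true, abs=1e-10)

    def test_matches_wls_closed_form(self):
        gen = np.random.default_rng(1)
        bx = gen.uniform(0.05, 0.3, 5)
        by = 0.01 + 0.25 * bx + gen.normal(0, 0.01, 5)
        se_out = gen.uniform(0.005, 0.02, 5)
        h = make_harmonized(by / bx, se_out / bx, beta_exp=bx)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / se_out**2).fit()
        e = egger(h)
        assert e.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert e.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self):
        # mean pleiotropic shift 0.02 injected into every instrument
        gen = np.random.default_rng(42)
        reps = 200
        intercepts = []
        for _ in range(reps):
            bx = gen.uniform(0.1, 0.4, 30)
            se_out = np.full(30, 0.01)
            pleio = gen.normal(0.02, 0.005, 30)
            by = pleio + 0.1 * bx + gen.normal(0, se_out)
            h = make_harmonized(by / bx, se_out / bx, beta_exp=bx)
            intercepts.append(egger(h).intercept)
        assert np.mean(intercepts) == pytest.approx(0.02, abs=0.005)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            egger(make_harmonized([0.1, 0.2], [0.02, 0.02]))


class TestWeightedMedian:
    def test_equal_weights_odd_count(self):
        assert _weighted_median_point(
            np.array([0.1, 0.2, 0.9]), np.ones(3)
        ) == pytest.approx(0.2)

    def test_equal_weights_equals_interpolated_median(self, rng):
        for n in (4, 7, 10):
            x = rng.normal(0, 1, n)
            assert _weighted_median_point(x, np.ones(n)) == pytest.approx(
                float(np.median(x)), abs=1e-12
            )

    def test_breakdown_robustness_vs_ivw(self):
        # just under half the instruments invalid, strong directional pleiotropy
        gen = np.random.default_rng(2024)
        reps = 200
        wm_err, ivw_err = [], []
        for _ in range(reps):
            n = 30
            n_invalid = 12  # 40% by count: invalid *weight* stays below 50%
            bx = gen.uniform(0.1, 0.4, n)
            se_out = np.full(n, 0.005)
            pleio = np.zeros(n)
            pleio[:n_invalid] = gen.normal(0.06, 0.01, n_invalid)
            by = pleio + 0.1 * bx + gen.normal(0, se_out)
            h = make_harmonized(by / bx, se_out / bx, beta_exp=bx)
            r = ratio_estimates(h)
            wald, wald_se = r["wald"].to_numpy(), r["wald_se"].to_numpy()
            wm = _weighted_median_point(wald, 1 / wald_se**2)
            iv = ivw(h).beta
            wm_err.append(wm - 0.1)
            ivw_err.append(iv - 0.1)
        assert abs(np.mean(ivw_err)) > 0.05
        assert abs(np.mean(wm_err)) < 0.03

    def test_bootstrap_se_converges(self, small_harmonized):
        e1 = weighted_median(small_harmonized, boot_reps=1000, seed=10)
        e2 = weighted_median(small_harmonized, boot_reps=2000, seed=11)
        assert abs(e2.se - e1.se) / e1.se < 0.05

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            weighted_median(make_harmonized([0.1, 0.2], [0.01, 0.01]))


class TestModeEstimate:
    def test_degenerate_all_equal(self):
        h = make_harmonized([0.25] * 4, [0.01] * 4)
        e = mode_estimate(h, boot_reps=50, seed=0)
        assert e.beta == pytest.approx(0.25)

    def test_plurality_valid_mixture(self, rng):
        wald = np.concatenate([rng.normal(0.1, 0.01, 18), rng.normal(0.5, 0.01, 12)])
        h = make_harmonized(wald, np.full(30, 0.02))
        e = mode_estimate(h, weighted=False, boot_reps=50, seed=0)
        assert abs(e.beta - 0.1) < 0.05

    def test_argmax_matches_dense_grid_oracle(self, rng):
        wald = rng.normal(0.2, 0.05, 10)
        weights = np.ones(10)
        est = _mode_point(wald, weights, 1.0, grid_points=512)
        bw = 1.0 * 0.9 * 1.4826 * np.median(np.abs(wald - np.median(wald))) * 10 ** (-0.2)
        dense = np.arange(wald.min() - 3 * bw, wald.max() + 3 * bw, 1e-4)
        oracle = dense[np.argmax(kernel_density(dense, wald, weights, bw))]
        coarse_step = (wald.max() - wald.min() + 6 * bw) / 511
        assert abs(est - oracle) <= coarse_step

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            mode_estimate(make_harmonized([0.1, 0.2], [0.01, 0.01]))


class TestOddsRatio:
    def test_published_beta_to_or_identities(self):
        from mrtriad.estimators import MREstimate

        for beta, expected in [(-0.0704, 0.932), (0.1020, 1.107), (0.1162, 1.123)]:
            e = MREstimate("ivw", beta, 0.01, 0.5, 10)
            assert round(to_odds_ratio(e)["or"], 3) == expected

    def test_zero_beta_gives_unit_or(self):
        from mrtriad.estimators import MREstimate

        e = MREstimate("ivw", 0.0, 0.1, 1.0, 5)
        assert to_odds_ratio(e)["or"] == pytest.approx(1.0)

    def test_ci_bounds(self):
        from mrtriad.estimators import MREstimate

        e = MREstimate("ivw", 0.1, 0.05, 0.05, 5)
        o = to_odds_ratio(e)
        assert o["or_low"] == pytest.approx(np.exp(0.1 - 1.96 * 0.05))
        assert o["or_high"] == pytest.approx(np.exp(0.1 + 1.96 * 0.05))


class TestSignFlipEquivariance:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_all_estimators_invariant_under_joint_sign_flip(self, seed):
        gen = np.random.default_rng(seed)
        n = 8
        bx = gen.uniform(0.05, 0.3, n)
        by = 0.15 * bx + gen.normal(0, 0.01, n)
        se_out = gen.uniform(0.005, 0.02, n)
        h = make_harmonized(by / bx, se_out / bx, beta_exp=bx)
        h_flip = make_harmonized(by / bx, se_out / bx, beta_exp=-bx)
        for a, b in zip(
            all_estimates(h, boot_reps=50, seed=1),
            all_estimates(h_flip, boot_reps=50, seed=1),
        ):
            assert a.beta == pytest.approx(b.beta, abs=1e-9)


def test_null_calibration_small():
    # no pleiotropy, true effect 0: |z| < 1.96 should hold ~95% of the time
    gen = np.random.default_rng(99)
    hits = 0
    reps = 200
    for _ in range(reps):
        n = 50
        bx = gen.uniform(0.1, 0.4, n)
        se_out = np.full(n, 0.01)
        by = gen.normal(0, se_out)
        h = make_harmonized(by / bx, se_out / bx, beta_exp=bx)
        e = ivw(h)
        hits += abs(e.beta / e.se) < 1.96
    assert 0.90 <= hits / reps <= 0.99
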