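"""Univariable estimators against closed forms, grid oracles, and simulations."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_hset, simulated_edge
from netmr import (
    IVW,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    MaximumLikelihood,
    MREgger,
    RAPS,
    cochran_q,
    leave_one_out,
    power_binary,
    steiger_test,
    wald_ratio,
)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [
            (1.0, 0.3, 0.1, 0.3, 0.1),
            (0.5, 0.1, 0.02, 0.2, 0.04),
            (-0.4, 0.2, 0.1, -0.5, 0.25),
        ],
    )
    def test_closed_form(self, bx, by, sy, beta, se):
        est = wald_ratio(bx, 0.0, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.0, 0.1, 0.1)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        hs = make_hset([0.4], [0.2], [0.1])
        est = IVW(hs).fit(model="fixed")
        ref = wald_ratio(0.4, 0.0, 0.2, 0.1)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_two_snp_hand_wls(self):
        # weights {100, 400}: beta = (100*.4*.2 + 400*.2*.05)/(100*.16 + 400*.04)
        hs = make_hset([0.4, 0.2], [0.2, 0.05], [0.1, 0.05])
        est = IVW(hs).fit(model="fixed")
        assert est.beta == pytest.approx(12.0 / 32.0)
        assert est.se == pytest.approx(32.0**-0.5)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            j = rng.integers(3, 12)
            hs = make_hset(
                rng.uniform(0.05, 0.5, j),
                rng.normal(0, 0.2, j),
                rng.uniform(0.01, 0.1, j),
            )
            fe = IVW(hs).fit(model="fixed")
            re = IVW(hs).fit(model="multiplicative_random")
            assert re.se >= fe.se
            assert re.beta == pytest.approx(fe.beta)

    def test_auto_switches_on_heterogeneity(self):
        homogeneous = make_hset([0.2, 0.3, 0.4], [0.02, 0.03, 0.04], [0.01] * 3)
        assert IVW(homogeneous).fit(model="auto").model == "fixed"
        heterogeneous = make_hset([0.2, 0.3, 0.4], [0.2, -0.3, 0.1], [0.01] * 3)
        fit = IVW(heterogeneous).fit(model="auto")
        assert fit.model == "multiplicative_random"
        assert fit.heterogeneity.pval < 0.05

    def test_recovers_simulated_truth(self, clean_edge):
        hs, truth = clean_edge
        est = IVW(hs).fit(model="auto")
        assert abs(est.beta - truth.delta_total) < 3 * est.se

    def test_insufficient_instruments(self):
        hs = make_hset([0.4], [0.2], [0.1])
        with pytest.raises(InsufficientInstrumentsError):
            IVW(hs).fit(model="multiplicative_random")


class TestEgger:
    def test_exact_line_through_two_points(self):
        hs = make_hset([0.2, 0.4], [0.05, 0.09], [0.1, 0.2])
        fit = MREgger(hs).fit(min_snp=2)
        assert fit.beta == pytest.approx(0.2)
        assert fit.pleiotropy.intercept == pytest.approx(0.01)
        assert fit.heterogeneity.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_statsmodels_wls(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        j = 30
        bx = rng.uniform(0.05, 0.5, j)
        sy = rng.uniform(0.02, 0.08, j)
        by = 0.3 * bx + 0.01 + rng.normal(0, sy)
        hs = make_hset(bx, by, sy)
        fit = MREgger(hs).fit()
        x = np.column_stack([np.ones(j), bx])
        ref = sm.WLS(by, x, weights=1.0 / sy**2).fit()
        assert fit.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert fit.pleiotropy.intercept == pytest.approx(ref.params[0], rel=1e-10)
        # statsmodels scales SEs by sqrt(Q/(J-2)); ours apply the >=1 floor
        scale = math.sqrt(ref.scale)
        assert fit.se == pytest.approx(
            ref.bse[1] / scale * max(1.0, scale), rel=1e-8
        )

    def test_orientation_invariance(self):
        rng = np.random.default_rng(8)
        j = 15
        bx = rng.normal(0, 0.3, j)
        sy = rng.uniform(0.02, 0.08, j)
        by = 0.25 * bx + rng.normal(0, sy)
        hs = make_hset(bx, by, sy)
        flipped = make_hset(-bx, -by, sy)
        a, b = MREgger(hs).fit(), MREgger(flipped).fit()
        assert a.beta == pytest.approx(b.beta)
        assert a.pleiotropy.intercept == pytest.approx(b.pleiotropy.intercept)

    def test_intercept_null_calibration_and_directional_recovery(self):
        # balanced pleiotropy: intercept test rejects at ~5%
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 500
        j = 40
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.4, j)
            sy = np.full(j, 0.03)
            pleio = rng.normal(0.0, 0.02, j)
            by = 0.2 * bx + pleio + rng.normal(0, sy)
            fit = MREgger(make_hset(bx, by, sy)).fit()
            rejections += fit.pleiotropy.pval < 0.05
        assert 0.02 <= rejections / reps <= 0.09

        # directional pleiotropy: mean intercept estimate near the true mean
        rng = np.random.default_rng(12)
        intercepts = []
        for _ in range(300):
            bx = rng.uniform(0.05, 0.4, j)
            sy = np.full(j, 0.03)
            pleio = rng.normal(0.02, 0.01, j)
            by = 0.2 * bx + pleio + rng.normal(0, sy)
            intercepts.append(MREgger(make_hset(bx, by, sy)).fit().pleiotropy.intercept)
        mc_se = np.std(intercepts) / math.sqrt(len(intercepts))
        assert abs(np.mean(intercepts) - 0.02) < 2 * mc_se


class TestMaximumLikelihood:
    def test_no_measurement_error_limit_equals_ivw(self):
        hs = make_hset([0.2, 0.35, 0.5], [0.05, 0.06, 0.12], [0.02, 0.03, 0.04])
        ml = MaximumLikelihood(hs).fit()
        ivw = IVW(hs).fit(model="fixed")
        assert ml.beta == pytest.approx(ivw.beta, abs=1e-6)
        assert ml.se == pytest.approx(ivw.se, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        hs = make_hset(
            [0.3, 0.15], [0.09, 0.02], [0.05, 0.03], sx=[0.04, 0.05]
        )
        ml = MaximumLikelihood(hs).fit()
        grid = np.arange(-2.0, 2.0, 1e-4)
        nll = [
            np.sum(
                (hs.beta_outcome - t * hs.beta_exposure) ** 2
                / (hs.se_outcome**2 + t**2 * hs.se_exposure**2)
            )
            for t in grid
        ]
        assert ml.beta == pytest.approx(grid[int(np.argmin(nll))], abs=2e-4)

    def test_recovers_simulated_truth(self):
        hs, truth = simulated_edge(seed=3, theta=0.5, m_snps=200,
                                   n_exposure=400_000, n_outcome=250_000)
        ml = MaximumLikelihood(hs).fit()
        assert abs(ml.beta - truth.delta_total) < 3 * ml.se


class TestRAPS:
    def test_l2_no_overdispersion_reduces_to_ivw(self):
        hs = make_hset([0.2, 0.35, 0.5], [0.05, 0.06, 0.12], [0.02, 0.03, 0.04])
        raps = RAPS(hs).fit(loss="l2", overdispersion=False)
        ivw = IVW(hs).fit(model="fixed")
        assert raps.beta == pytest.approx(ivw.beta, abs=1e-6)
        assert raps.extra["tau2"] == 0.0

    def test_ci_coverage_under_balanced_pleiotropy(self):
        rng = np.random.default_rng(5)
        j, reps = 150, 200
        covered = 0
        for _ in range(reps):
            bx_true = rng.uniform(0.05, 0.3, j)
            sx = np.full(j, 0.01)
            sy = np.full(j, 0.02)
            pleio = rng.normal(0.0, 0.01, j)
            bx = bx_true + rng.normal(0, sx)
            by = 0.3 * bx_true + pleio + rng.normal(0, sy)
            hs = make_hset(bx, by, sy, sx=sx)
            fit = RAPS(hs).fit(loss="l2", overdispersion=True)
            lo, hi = fit.conf_int()
            covered += lo <= 0.3 <= hi
        assert covered / reps >= 0.90

    def test_huber_resists_gross_outlier(self):
        rng = np.random.default_rng(17)
        j = 60
        bx = rng.uniform(0.1, 0.4, j)
        sx = np.full(j, 0.005)
        sy = np.full(j, 0.02)
        by = 0.25 * bx + rng.normal(0, sy)
        by[0] += 0.5  # gross pleiotropic outlier
        hs = make_hset(bx + rng.normal(0, sx), by, sy, sx=sx)
        l2 = RAPS(hs).fit(loss="l2")
        huber = RAPS(hs).fit(loss="huber")
        assert abs(huber.beta - 0.25) < abs(l2.beta - 0.25)


class TestCochranQ:
    def test_perfect_fit_gives_zero_q(self):
        hs = make_hset([0.2, 0.3, 0.4], [0.1, 0.15, 0.2], [0.02, 0.05, 0.04])
        res = cochran_q(hs, around="ivw")
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)
        assert res.df == 2

    def test_hand_instance(self):
        bx = np.array([0.2, 0.4, 0.3])
        by = np.array([0.06, 0.1, 0.12])
        sy = np.array([0.02, 0.04, 0.03])
        w = 1 / sy**2
        theta = np.sum(w * bx * by) / np.sum(w * bx**2)
        expected = float(np.sum(w * (by - theta * bx) ** 2))
        res = cochran_q(make_hset(bx, by, sy), around="ivw")
        assert res.q == pytest.approx(expected)
        assert res.pval == pytest.approx(float(stats.chi2.sf(expected, 2)))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(23)
        pvals = []
        j = 25
        for _ in range(500):
            bx = rng.uniform(0.1, 0.5, j)
            sy = rng.uniform(0.02, 0.05, j)
            by = 0.2 * bx + rng.normal(0, sy)
            pvals.append(cochran_q(make_hset(bx, by, sy)).pval)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_egger_df(self):
        hs = make_hset([0.2, 0.3, 0.4, 0.1], [0.1, 0.2, 0.1, 0.05], [0.03] * 4)
        assert cochran_q(hs, around="egger").df == 2


class TestSteiger:
    def test_exposure_dominates(self, clean_edge):
        hs, _ = clean_edge
        res = steiger_test(hs)
        assert res.direction_correct
        assert res.r2_exposure > res.r2_outcome
        assert res.pval < 1e-6

    def test_symmetry_gives_p_one(self):
        hs = make_hset([0.2, 0.3], [0.2, 0.3], [0.01, 0.01], sx=[0.01, 0.01])
        res = steiger_test(hs, n_exposure=50_000, n_outcome=50_000)
        assert res.pval == pytest.approx(1.0)
        assert not res.direction_correct

    def test_correct_direction_in_most_replicates(self):
        correct = 0
        for s in range(100):
            hs, _ = simulated_edge(seed=900 + s, theta=0.3, m_snps=25)
            correct += steiger_test(hs).direction_correct
        assert correct >= 95


class TestLeaveOneOut:
    def test_identical_snps_exchangeable(self):
        hs = make_hset([0.3] * 5, [0.09] * 5, [0.02] * 5)
        table = leave_one_out(hs)
        full = IVW(hs).fit(model="auto")
        assert np.allclose(table["beta"], full.beta)
        assert not table["flagged"].any()

    def test_rows_equal_direct_subset_fits(self):
        hs = make_hset([0.2, 0.4, 0.3], [0.05, 0.1, 0.12], [0.02, 0.04, 0.03])
        table = leave_one_out(hs, model="fixed")
        for i in range(3):
            sub = hs.subset([j for j in range(3) if j != i])
            direct = IVW(sub).fit(model="fixed")
            assert table.loc[i, "beta"] == pytest.approx(direct.beta)
            assert table.loc[i, "se"] == pytest.approx(direct.se)

    def test_outlier_row_is_the_extreme(self):
        hs, _ = simulated_edge(seed=31, theta=0.2, m_snps=20)
        by = hs.beta_outcome.copy()
        by[4] += 12 * hs.se_outcome[4]
        hs.beta_outcome = by
        table = leave_one_out(hs)
        full = IVW(hs).fit(model="auto")
        dev = np.abs(table["beta"] - full.beta)
        assert table.loc[int(np.argmax(dev)), "left_out_variant"] == hs.snp_ids[4]


class TestPower:
    def test_null_or_gives_alpha(self):
        res = power_binary(0.03, 100_000, 0.35, assumed_or=1.0, alpha=0.05)
        assert res.power == pytest.approx(0.05)

    def test_large_n_limit(self):
        res = power_binary(0.03, 10**9, 0.35, assumed_or=1.2)
        assert res.power == pytest.approx(1.0)

    def test_against_monte_carlo_ivw_oracle(self):
        # simulate the whole IVW z-test at the implied instrument strength
        n, cf, or_, r2 = 150_000, 0.35, 1.15, 0.02
        j, maf = 10, 0.3
        # equal instruments explaining r2 of the exposure in total
        bx = math.sqrt(r2 / (j * 2 * maf * (1 - maf)))
        se_out = 1.0 / math.sqrt(2 * maf * (1 - maf) * n * cf * (1 - cf))
        rng = np.random.default_rng(42)
        theta = math.log(or_)
        rej = 0
        reps = 2000
        for _ in range(reps):
            by = theta * bx + rng.normal(0, se_out, j)
            w = 1.0 / se_out**2
            beta = np.sum(w * bx * by) / (j * w * bx**2)
            z = beta / (j * w * bx**2) ** -0.5
            rej += abs(z) > stats.norm.ppf(0.975)
        analytic = power_binary(r2, n, cf, assumed_or=or_).power
        assert abs(analytic - rej / reps) < 0.03
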