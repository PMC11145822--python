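"""Multivariable MR: joint IVW/Egger, conditional F, MR-Lasso, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlipid.estimators import EstimatorError, ivw_fit
from mrlipid.mvmr import (
    MVInstrumentSet,
    conditional_f,
    mr_lasso,
    mvmr_egger,
    mvmr_ivw,
    pool_instruments,
)
from mrlipid.synthetic import mvmr_attenuation_config, simulate_arrays


def mvset(BX, by, sy, SX=None, names=None):
    BX = np.atleast_2d(np.asarray(BX, dtype=float))
    n, k = BX.shape
    SX = np.full((n, k), 0.01) if SX is None else np.asarray(SX, dtype=float)
    names = names or [f"x{j}" for j in range(k)]
    return MVInstrumentSet(
        [f"rs{i}" for i in range(n)], names, BX, SX,
        np.asarray(by, dtype=float), np.asarray(sy, dtype=float),
    )


def random_mv_instance(data, max_snps=50, max_k=3):
    k = data.draw(st.integers(1, max_k))
    n = data.draw(st.integers(k + 2, max_snps))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    BX = rng.normal(0, 1, (n, k))
    by = rng.normal(0, 0.5, n)
    sy = rng.uniform(0.05, 0.5, n)
    return BX, by, sy


class TestMVIVW:
    def test_exact_linear_system(self):
        rng = np.random.default_rng(0)
        BX = rng.normal(0, 1, (20, 2))
        by = 0.005 * BX[:, 0] + 0.002 * BX[:, 1]
        res = mvmr_ivw(mvset(BX, by, np.full(20, 0.01)))
        assert res.estimates[0].theta == pytest.approx(0.005, rel=1e-10)
        assert res.estimates[1].theta == pytest.approx(0.002, rel=1e-10)
        assert res.Q == pytest.approx(0.0, abs=1e-16)

    def test_single_exposure_reduces_to_ivw(self):
        rng = np.random.default_rng(1)
        bx = rng.normal(0, 1, 10)
        by = 0.4 * bx + rng.normal(0, 0.05, 10)
        sy = np.full(10, 0.05)
        res = mvmr_ivw(mvset(bx[:, None], by, sy))
        theta, se, _ = ivw_fit(bx, by, sy)
        assert res.estimates[0].theta == pytest.approx(theta, rel=1e-12)

    def test_collinear_exposures_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 10)
        BX = np.column_stack([x, 2.0 * x])
        with pytest.raises(EstimatorError, match="collinear"):
            mvmr_ivw(mvset(BX, x, np.full(10, 0.1)))

    def test_needs_more_snps_than_exposures(self):
        BX = np.eye(2)
        with pytest.raises(EstimatorError, match="nsnp > K"):
            mvmr_ivw(mvset(BX, [0.1, 0.2], [0.1, 0.1]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_wls_oracle(self, data):
        import statsmodels.api as sm

        BX, by, sy = random_mv_instance(data)
        res = mvmr_ivw(mvset(BX, by, sy))
        fit = sm.WLS(by, BX, weights=1.0 / sy**2).fit()
        for j, est in enumerate(res.estimates):
            assert est.theta == pytest.approx(fit.params[j], rel=1e-10)
            infl = max(1.0, np.sqrt(res.Q / res.Q_df))
            se_oracle = float(np.sqrt(fit.normalized_cov_params[j, j])) * infl
            assert est.se == pytest.approx(se_oracle, rel=1e-10)

    def test_uni_vs_mv_agree_with_independent_columns(self):
        """With independent effect columns and no pleiotropy, the same
        exposure's uni- and multivariable estimates coincide within noise."""
        rng = np.random.default_rng(42)
        uni_minus_mv = []
        for _ in range(60):
            BX = rng.normal(0, 1, (80, 2))
            sy = np.full(80, 0.1)
            by = 0.3 * BX[:, 0] + rng.normal(0, 0.1, 80)
            theta_uni, _, _ = ivw_fit(BX[:, 0], by, sy)
            res = mvmr_ivw(mvset(BX, by, sy))
            uni_minus_mv.append(theta_uni - res.estimates[0].theta)
        arr = np.array(uni_minus_mv)
        mcse = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean()) < 3 * mcse + 1e-12

    def test_mv_removes_confounded_path_bias(self):
        """Exposure 2 proxies exposure 1; univariable MR on it is biased,
        multivariable MR is null-centred (the HDL-C/TG attenuation shape)."""
        cfg = mvmr_attenuation_config()
        uni2, mv2 = [], []
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            a = simulate_arrays(cfg, rng)
            t_uni, _, _ = ivw_fit(a.bx_obs[:, 1], a.by_obs, a.sy)
            res = mvmr_ivw(
                mvset(a.bx_obs, a.by_obs, a.sy, SX=a.sx,
                      names=list(cfg.names()))
            )
            uni2.append(t_uni)
            mv2.append(res.estimate_for("HDL-C").theta)
        uni2, mv2 = np.array(uni2), np.array(mv2)
        assert abs(uni2.mean()) > 5 * uni2.std(ddof=1) / np.sqrt(uni2.size)
        assert abs(mv2.mean()) < 3 * mv2.std(ddof=1) / np.sqrt(mv2.size)
        assert np.mean(np.abs(mv2)) < np.mean(np.abs(uni2))


class TestMVEgger:
    def test_exact_fit_with_intercept(self):
        rng = np.random.default_rng(3)
        BX = np.abs(rng.normal(1, 0.3, (20, 2)))
        by = 0.01 + 0.005 * BX[:, 0] + 0.002 * BX[:, 1]
        res = mvmr_egger(mvset(BX, by, np.full(20, 0.01)))
        assert res.egger_intercept[0] == pytest.approx(0.01, rel=1e-8)
        assert res.estimates[0].theta == pytest.approx(0.005, rel=1e-8)

    def test_minimum_snp_count(self):
        BX = np.random.default_rng(4).normal(0, 1, (3, 2))
        with pytest.raises(EstimatorError, match="K \\+ 1"):
            mvmr_egger(mvset(BX, [0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))

    def test_anchor_choice_slope_stability(self):
        # exact-fit instance: slopes identical whichever exposure anchors
        rng = np.random.default_rng(5)
        BX = np.abs(rng.normal(1, 0.3, (20, 2)))
        by = 0.01 + 0.005 * BX[:, 0] + 0.002 * BX[:, 1]
        s = mvset(BX, by, np.full(20, 0.01))
        res0 = mvmr_egger(s, anchor=0)
        res1 = mvmr_egger(s, anchor=1)
        for a, b in zip(res0.estimates, res1.estimates):
            assert a.theta == pytest.approx(b.theta, rel=1e-8)


class TestConditionalF:
    def test_orthogonal_equal_strength_near_marginal(self):
        rng = np.random.default_rng(6)
        n = 4000
        BX = rng.normal(0, 1.0, (n, 2))
        SX = np.full((n, 2), 0.2)
        BXo = BX + rng.normal(0, 0.2, (n, 2))
        s = mvset(BXo, rng.normal(0, 0.1, n), np.full(n, 0.1), SX=SX)
        condF = conditional_f(s)
        marginal = float(np.mean((BXo[:, 0] / 0.2) ** 2))
        assert condF["x0"] == pytest.approx(marginal, rel=0.10)

    def test_duplicated_exposure_collapses(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        BX = np.column_stack([x, x])
        s = mvset(BX, rng.normal(0, 0.1, 50), np.full(50, 0.1))
        condF = conditional_f(s)
        assert condF["x0"] < 1e-10 and condF["x1"] < 1e-10

    def test_weak_member_flagged(self):
        rng = np.random.default_rng(8)
        n = 200
        strong = rng.normal(0, 1.0, n)
        weak = rng.normal(0, 0.05, n)
        BX = np.column_stack([strong, weak])
        SX = np.full((n, 2), 0.1)
        s = mvset(BX, rng.normal(0, 0.1, n), np.full(n, 0.1), SX=SX)
        condF = conditional_f(s)
        assert condF["x0"] > 10.0
        assert condF["x1"] < 10.0


class TestMRLasso:
    def _instance(self, n=40, outlier=None, seed=9):
        rng = np.random.default_rng(seed)
        bx = rng.normal(2.5, 0.8, n) * rng.choice([-1, 1], n)
        sy = np.full(n, 0.05)
        by = 0.3 * bx + rng.normal(0, 0.05, n)
        if outlier is not None:
            by[5] += outlier
        return mvset(bx[:, None], by, sy)

    def test_infinite_penalty_equals_ivw(self):
        s = self._instance()
        res = mr_lasso(s, lambda_grid=[1e12])
        ref = mvmr_ivw(s)
        assert res.nsnp == s.nsnp and not res.excluded_snps
        assert res.estimates[0].theta == pytest.approx(
            ref.estimates[0].theta, rel=1e-12
        )

    def test_planted_outlier_excluded_and_estimate_recovers(self):
        s = self._instance(outlier=0.5)  # 10x the outcome SE
        res = mr_lasso(s)
        assert "rs5" in res.excluded_snps
        assert res.estimates[0].theta == pytest.approx(0.3, abs=0.02)

    def test_zero_lambda_rejected(self):
        s = self._instance(n=4)
        with pytest.raises(EstimatorError, match="unidentified"):
            mr_lasso(s, lambda_grid=[0.0])

    def test_valid_set_grows_with_lambda(self):
        from mrlipid.mvmr import _lasso_path_fit

        s = self._instance(outlier=0.5)
        X, y, w = s.beta_exps, s.beta_out, 1.0 / s.se_out**2
        sizes = []
        alpha = np.zeros(s.nsnp)
        theta = np.zeros(s.K)
        for lam in np.geomspace(1e-4, 1e4, 15):
            alpha, theta = _lasso_path_fit(X, y, w, lam, alpha, theta)
            sizes.append(int(np.sum(np.abs(alpha) < 1e-12)))
        assert sizes == sorted(sizes)


class TestPooling:
    def test_pooled_instruments_cover_all_exposures(self, paper_study):
        mv = pool_instruments(
            paper_study.exposures, paper_study.outcome, paper_study.ld
        )
        assert mv.K == 3
        assert mv.nsnp > 50
        assert np.all(mv.se_exps > 0)
        # pooled set must be clumped: mutual r2 below threshold
        for i, a in enumerate(mv.snp_ids[:40]):
            for b in mv.snp_ids[i + 1:40]:
                assert paper_study.ld.r2(a, b) < 0.001 or a == b
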