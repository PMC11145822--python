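"""Univariable estimators: Wald, IVW, Egger, medians, leave-one-out."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlipid.estimators import (
    EstimatorError,
    egger,
    egger_fit,
    ivw,
    ivw_fit,
    leave_one_out,
    median_estimator,
    scatter_funnel_tables,
    wald_ratio,
    weighted_median_fit,
)

from conftest import make_iset


def random_instance(data, max_snps=50):
    n = data.draw(st.integers(3, max_snps))
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    bx = rng.normal(0, 1, n)
    bx[np.abs(bx) < 1e-3] += 0.1
    by = rng.normal(0, 0.5, n)
    sy = rng.uniform(0.05, 0.5, n)
    return bx, by, sy


class TestWaldRatio:
    def test_arithmetic(self):
        iset = make_iset([0.1], [0.05], [0.01])
        est = wald_ratio(iset.instruments[0])
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low == pytest.approx(0.5 - 1.96 * 0.1, abs=1e-3)

    def test_null_outcome(self):
        iset = make_iset([0.1], [0.0], [0.01])
        est = wald_ratio(iset.instruments[0])
        assert est.theta == 0.0 and est.pval == pytest.approx(1.0)

    def test_null_instrument_rejected(self):
        iset = make_iset([0.0], [0.05], [0.01])
        with pytest.raises(EstimatorError, match="null instrument"):
            wald_ratio(iset.instruments[0])

    def test_orientation_invariance(self):
        a = wald_ratio(make_iset([0.1], [0.05], [0.01]).instruments[0])
        b = wald_ratio(make_iset([-0.1], [-0.05], [0.01]).instruments[0])
        assert a.theta == b.theta and a.se == b.se


class TestIVW:
    def test_identical_ratios_zero_heterogeneity(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        est, het = ivw(iset)
        assert est.theta == pytest.approx(0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.df == 1

    def test_closed_form_by_hand(self):
        # sum(w bx^2) = (0.01 + 0.04) / 1e-4 = 500
        iset = make_iset([0.1, 0.2], [0.05, 0.10], [0.01, 0.01])
        est, _ = ivw(iset)
        assert est.theta == pytest.approx(0.5, rel=1e-12)
        assert est.se == pytest.approx(500**-0.5, rel=1e-12)

    def test_q_statistic_by_hand(self):
        # ratios 0.4 and 0.6 with ratio SEs 0.1: Q = 2.0
        iset = make_iset([1.0, 1.0], [0.4, 0.6], [0.1, 0.1])
        _, het = ivw(iset)
        assert het.Q == pytest.approx(2.0, rel=1e-12)

    def test_single_snp_equals_wald(self):
        iset = make_iset([0.1], [0.07], [0.02])
        est, _ = ivw(iset)
        wald = wald_ratio(iset.instruments[0])
        assert est.theta == wald.theta and est.se == wald.se

    def test_random_effects_inflation(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.2, 0.5, 0.8], [0.1, 0.1, 0.1])
        fe, het = ivw(iset, model="fixed")
        mre, _ = ivw(iset, model="multiplicative_random")
        assert mre.theta == fe.theta
        assert mre.se == pytest.approx(fe.se * np.sqrt(het.Q / het.df))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_wls_oracle(self, data):
        import statsmodels.api as sm

        bx, by, sy = random_instance(data)
        theta, se, Q = ivw_fit(bx, by, sy)
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert theta == pytest.approx(fit.params[0], rel=1e-10)
        # fixed-effect SE: unscaled (X' W X)^{-1/2}
        se_oracle = float(np.sqrt(fit.normalized_cov_params[0, 0]))
        assert se == pytest.approx(se_oracle, rel=1e-10)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_invariance_to_orientation_and_order(self, data):
        bx, by, sy = random_instance(data, max_snps=20)
        theta, se, Q = ivw_fit(bx, by, sy)
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        flip = rng.choice([-1.0, 1.0], bx.size)
        perm = rng.permutation(bx.size)
        theta2, se2, Q2 = ivw_fit((bx * flip)[perm], (by * flip)[perm], sy[perm])
        assert theta2 == pytest.approx(theta, rel=1e-12)
        assert Q2 == pytest.approx(Q, rel=1e-9)


class TestEgger:
    def test_exact_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.5 * bx
        iset = make_iset(bx, by, [0.01] * 4)
        est, pleio, het = egger(iset)
        assert est.theta == pytest.approx(0.5, rel=1e-10)
        assert pleio.intercept == pytest.approx(0.01, rel=1e-10)
        assert het.Q == pytest.approx(0.0, abs=1e-18)

    def test_requires_three_instruments(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(EstimatorError, match="3 instruments"):
            egger(iset)

    def test_reorientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = np.array([0.06, -0.09, 0.16, 0.21])
        a = egger(make_iset(bx, by, [0.01] * 4))
        b = egger(make_iset(-bx, -by, [0.01] * 4))
        assert a[0].theta == pytest.approx(b[0].theta, rel=1e-12)
        assert a[1].intercept == pytest.approx(b[1].intercept, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_wls_oracle(self, data):
        import statsmodels.api as sm

        bx, by, sy = random_instance(data)
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        slope, se_slope, intercept, se_int, Q = egger_fit(bx, by, sy)
        X = sm.add_constant(bxo[:, None])
        fit = sm.WLS(byo, X, weights=1.0 / sy**2).fit()
        assert slope == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept == pytest.approx(fit.params[0], rel=1e-10)
        n = bx.size
        infl = max(1.0, np.sqrt(Q / (n - 2)))
        assert se_slope == pytest.approx(
            float(np.sqrt(fit.normalized_cov_params[1, 1])) * infl, rel=1e-10
        )


class TestMedians:
    def test_simple_median_middle_ratio(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [0.1, 0.1, 0.1])
        est = median_estimator(iset, "simple", n_boot=0)
        assert est.theta == pytest.approx(0.5)

    def test_weighted_median_interpolation(self):
        # ratios (1,2,3), normalized weights (0.2,0.3,0.5):
        # s = (0.1, 0.35, 0.75); crossing 0.5 between ratios 2 and 3 -> 2.375
        ratios = np.array([1.0, 2.0, 3.0])
        weights = np.array([0.2, 0.3, 0.5])
        assert weighted_median_fit(ratios, weights) == pytest.approx(2.375)

    def test_weighted_median_via_estimator(self):
        # bx = 1 so ratios = by; sy chosen so (bx/sy)^2 gives weights 2:3:5
        w = np.array([0.2, 0.3, 0.5])
        iset = make_iset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], 1.0 / np.sqrt(w))
        est = median_estimator(iset, "weighted", n_boot=0)
        assert est.theta == pytest.approx(2.375)

    def test_bootstrap_determinism_and_stability(self):
        rng = np.random.default_rng(7)
        bx = rng.normal(2.5, 0.5, 30)
        by = 0.5 * bx + rng.normal(0, 0.05, 30)
        iset = make_iset(bx, by, [0.05] * 30)
        a = median_estimator(iset, "weighted", n_boot=1000, seed=11)
        b = median_estimator(iset, "weighted", n_boot=1000, seed=11)
        c = median_estimator(iset, "weighted", n_boot=1000, seed=12)
        assert a.se == b.se
        assert a.se == pytest.approx(c.se, rel=0.20)

    def test_requires_three_instruments(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(EstimatorError):
            median_estimator(iset, "simple")


class TestLeaveOneOut:
    def test_identical_ratios_all_rows_equal_full(self):
        iset = make_iset([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], [0.01] * 3)
        full, _ = ivw(iset)
        rows = leave_one_out(iset)
        assert len(rows) == 3
        for row in rows:
            assert row["theta"] == pytest.approx(full.theta, rel=1e-12)
            assert not row["flagged"]

    def test_planted_outlier_has_max_delta(self):
        bx = np.full(10, 1.0)
        by = np.full(10, 0.5)
        by[3] = 3.0  # dominates Q
        iset = make_iset(bx, by, [0.05] * 10)
        rows = leave_one_out(iset)
        deltas = {r["excluded_snp"]: abs(r["delta_theta"]) for r in rows}
        assert max(deltas, key=deltas.get) == iset.snp_ids[3]


class TestPlotTables:
    def test_columns_complete(self):
        iset = make_iset([0.1, 0.2, 0.3], [0.05, 0.1, 0.2], [0.01] * 3)
        est, _ = ivw(iset)
        scatter, funnel, lines = scatter_funnel_tables(iset, [est])
        assert set(scatter.columns) >= {"beta_exp", "beta_out", "se_out"}
        assert set(funnel.columns) >= {"ratio", "precision"}
        assert lines.loc[0, "slope"] == est.theta

    def test_empty_set_rejected(self):
        from mrlipid.instruments import InstrumentSet

        with pytest.raises(EstimatorError):
            scatter_funnel_tables(InstrumentSet("x", []), None)

    def test_symmetric_funnel_centres_on_ivw(self):
        # symmetric ratios with equal precision: funnel mean equals IVW
        iset = make_iset([1.0, 1.0, 1.0, 1.0],
                         [0.4, 0.6, 0.45, 0.55], [0.1] * 4)
        est, _ = ivw(iset)
        _, funnel, _ = scatter_funnel_tables(iset, [est])
        assert funnel["ratio"].mean() == pytest.approx(est.theta, rel=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.data())
def test_all_estimators_invariant_to_allele_orientation(data):
    """Flipping any SNP's effect allele leaves every estimate unchanged."""
    bx, by, sy = random_instance(data, max_snps=15)
    rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
    flip = rng.choice([-1.0, 1.0], bx.size)
    a_set = make_iset(bx, by, sy)
    b_set = make_iset(bx * flip, by * flip, sy)
    ivw_a, _ = ivw(a_set)
    ivw_b, _ = ivw(b_set)
    assert ivw_a.theta == pytest.approx(ivw_b.theta, rel=1e-12)
    eg_a = egger(a_set)
    eg_b = egger(b_set)
    assert eg_a[0].theta == pytest.approx(eg_b[0].theta, rel=1e-10)
    assert eg_a[1].intercept == pytest.approx(eg_b[1].intercept, rel=1e-10)
    med_a = median_estimator(a_set, "weighted", n_boot=0)
    med_b = median_estimator(b_set, "weighted", n_boot=0)
    assert med_a.theta == pytest.approx(med_b.theta, rel=1e-12)
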