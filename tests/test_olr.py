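"""Proportional-odds fits, likelihood-ratio tests and DIF magnitudes."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest

from difagree import (
    DIFResultRow,
    classify_item,
    cvbl_delta_beta1,
    dif_statistics,
    fit_null_polr,
    fit_polr,
    lrt_chi2,
    mcfadden_delta_r2,
)
from difagree.olr import OLRFit


@pytest.fixture(scope="module")
def sim_item():
    rng = np.random.default_rng(12)
    n = 200
    trait = rng.normal(size=n)
    group = rng.integers(0, 2, n)
    lin = 1.4 * trait + 0.5 * group
    y = np.clip(np.round(lin + rng.logistic(size=n) * 0.8 + 2), 0, 4)
    return y, trait, group


class TestFits:
    def test_intercept_only_equals_cumulative_logits(self, sim_item):
        """With a constant trait, Model 1 collapses to the intercept-only
        model whose alphas are the empirical cumulative log-odds."""
        y, _, _ = sim_item
        null = fit_null_polr(y)
        m1 = fit_polr(y, np.zeros_like(y), model_id=1)
        n = y.size
        K = int(y.max()) + 1
        counts = np.bincount(y.astype(int), minlength=K)
        tail = np.cumsum(counts[::-1])[::-1]
        expected = np.log(tail[1:] / (n - tail[1:]))
        np.testing.assert_allclose(null.alpha, expected, atol=1e-10)
        np.testing.assert_allclose(m1.alpha, expected, atol=1e-5)
        assert m1.loglik == pytest.approx(null.loglik, abs=1e-6)

    def test_nesting_orders_logliks(self, sim_item):
        y, trait, group = sim_item
        m1 = fit_polr(y, trait, group, model_id=1)
        m2 = fit_polr(y, trait, group, model_id=2)
        m3 = fit_polr(y, trait, group, model_id=3)
        assert m1.loglik <= m2.loglik + 1e-9 <= m3.loglik + 2e-9

    def test_cross_fit_against_statsmodels(self, sim_item):
        """Coefficients and loglik match an independent optimizer to 4
        decimals (statsmodels OrderedModel, logit link)."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, trait, group = sim_item
        X = np.column_stack([trait, group, trait * group])
        mine = fit_polr(y, trait, group, model_id=3)
        sm = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0,
                                                   gtol=1e-9)
        assert mine.loglik == pytest.approx(sm.llf, abs=1e-4)
        np.testing.assert_allclose([mine.beta1, mine.beta2, mine.beta3],
                                   sm.params[:3], atol=1e-4)

    def test_degenerate_response_rejected(self):
        from difagree._exceptions import DataError

        with pytest.raises(DataError):
            fit_polr(np.ones(50), np.random.default_rng(0).normal(size=50))


class TestLRT:
    def _fit_pair(self, ll_small, ll_big):
        s = OLRFit(1, (0.0,), beta1=1.0, loglik=ll_small)
        b = OLRFit(2, (0.0,), beta1=1.0, beta2=0.0, loglik=ll_big)
        return s, b

    def test_identical_logliks_give_p_one(self):
        s, b = self._fit_pair(-100.0, -100.0)
        stat, p = lrt_chi2(s, b)
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("stat,expected_p", [(6.635, 0.01), (3.841, 0.05)])
    def test_chi2_tail_values(self, stat, expected_p):
        """Classical chi-square(1) critical values round-trip."""
        s, b = self._fit_pair(-100.0, -100.0 + stat / 2)
        got_stat, got_p = lrt_chi2(s, b)
        assert got_stat == pytest.approx(stat)
        assert got_p == pytest.approx(expected_p, abs=5e-4)
        # independent oracle: complement of the chi2 CDF
        assert got_p == pytest.approx(1 - chi2.cdf(stat, 1), abs=1e-12)

    def test_null_p_values_uniform(self):
        """Under a true null (trait known, no group effect) the uniform-DIF
        LRT p-value is uniform on [0, 1] (Kolmogorov-Smirnov)."""
        rng = np.random.default_rng(99)
        n, reps = 250, 500
        pvals = []
        for _ in range(reps):
            trait = rng.normal(size=n)
            group = rng.integers(0, 2, n)
            y = np.clip(np.round(1.3 * trait + 0.9 * rng.logistic(size=n) + 2),
                        0, 4)
            m1 = fit_polr(y, trait, group, model_id=1)
            m2 = fit_polr(y, trait, group, model_id=2)
            pvals.append(lrt_chi2(m1, m2)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestMagnitudes:
    def test_mcfadden_identity(self):
        null = OLRFit(0, (0.0,), loglik=-100.0)
        small = OLRFit(1, (0.0,), beta1=1.0, loglik=-80.0)
        big = OLRFit(2, (0.0,), beta1=1.0, beta2=0.5, loglik=-75.0)
        assert mcfadden_delta_r2(small, big, null) == pytest.approx(0.05)
        assert mcfadden_delta_r2(small, small, null) == 0.0

    def test_mcfadden_tracks_chi2_ordering(self, sim_item):
        """For a fixed null deviance, a larger chi-square implies a larger
        delta-R^2 (they are proportional)."""
        y, trait, group = sim_item
        null = fit_null_polr(y)
        m1 = fit_polr(y, trait, group, model_id=1)
        m2 = fit_polr(y, trait, group, model_id=2)
        stat, _ = lrt_chi2(m1, m2)
        dr2 = mcfadden_delta_r2(m1, m2, null)
        assert dr2 == pytest.approx(stat / (2 * abs(null.loglik)))

    @pytest.mark.parametrize("b1_m1,b1_m2,expected", [
        (1.0, 1.0, 0.0), (1.0, 0.9, 0.1), (2.0, 2.5, 0.25)])
    def test_cvbl_proportionate_change(self, b1_m1, b1_m2, expected):
        m1 = OLRFit(1, (0.0,), beta1=b1_m1, loglik=-10)
        m2 = OLRFit(2, (0.0,), beta1=b1_m2, beta2=0.1, loglik=-9)
        assert cvbl_delta_beta1(m1, m2) == pytest.approx(expected)

    def test_cvbl_undefined_for_zero_beta1(self):
        m1 = OLRFit(1, (0.0,), beta1=0.0, loglik=-10)
        m2 = OLRFit(2, (0.0,), beta1=0.2, beta2=0.1, loglik=-9)
        assert np.isnan(cvbl_delta_beta1(m1, m2))


class TestClassification:
    def _row(self, p_u, thr_u, p_nu, thr_nu, dr2_u=0.0, dr2_nu=0.0,
             t_dr2_u=np.inf, t_dr2_nu=np.inf):
        return DIFResultRow("it", p_u, p_nu, dr2_u, dr2_nu, 0.0,
                            thr_u, thr_nu, t_dr2_u, t_dr2_nu, np.inf)

    def test_uniform_flag(self):
        # the worked bath-item cell: p_unif 0.0002 < 0.0141,
        # p_nonunif 0.3156 >= 0.0107
        row = classify_item(self._row(0.0002, 0.0141, 0.3156, 0.0107,
                                      dr2_u=0.0243, t_dr2_u=0.0114))
        assert row.flag == "uniform"
        assert row.practically_important

    def test_nonuniform_subsumes_uniform(self):
        # both significant: non-uniform takes precedence
        row = classify_item(self._row(0.0000, 0.0110, 0.0029, 0.0327))
        assert row.flag == "nonuniform"

    def test_no_flag_when_neither_fires(self):
        row = classify_item(self._row(0.5, 0.01, 0.8, 0.01))
        assert row.flag == "none"
        assert not row.practically_important


def test_dif_statistics_detects_injected_group_shift():
    rng = np.random.default_rng(21)
    n = 1000
    trait = rng.normal(size=n)
    group = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    y = np.clip(np.round(1.4 * trait - 0.9 * group +
                         0.9 * rng.logistic(size=n) + 2), 0, 4)
    row = dif_statistics("it", y, trait, group)
    assert row.flag == "uniform"
    assert row.beta2 < 0
    assert row.delta_r2_uniform > 0
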