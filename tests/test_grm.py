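"""Graded response model: probabilities, EM calibration, EAP scoring."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from difagree import (
    GRMItemParams,
    collapse_sparse_categories,
    eap_score,
    fit_grm,
    grm_category_probs,
    grm_cumulative_prob,
)
from difagree._exceptions import DataError


def _simulate(rng, theta, a, b):
    p = grm_category_probs(theta, a, b)
    u = rng.random(theta.size)
    return (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1).astype(float)


class TestProbabilities:
    def test_logistic_midpoint(self):
        p = GRMItemParams("i", a=1.3, b=(-1.0, 0.2, 1.1))
        for k, bk in enumerate(p.b, start=1):
            assert grm_cumulative_prob(bk, p, k) == pytest.approx(0.5)

    def test_category_probs_sum_to_one(self):
        p = GRMItemParams("i", a=2.0, b=(-2, -1, 0, 1))
        theta = np.linspace(-5, 5, 31)
        probs = grm_category_probs(theta, p.a, p.b)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_matches_direct_logistic_evaluation(self):
        """a=1.7, b=(-2,-1,0,1), theta=0: probabilities by hand."""
        a, b = 1.7, np.array([-2.0, -1.0, 0.0, 1.0])
        cum = expit(a * (0.0 - b))          # independent evaluation
        expected = np.r_[1.0, cum] - np.r_[cum, 0.0]
        got = grm_category_probs(0.0, a, b)[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(DataError):
            GRMItemParams("i", a=1.0, b=(0.5, 0.5))
        with pytest.raises(DataError):
            GRMItemParams("i", a=-1.0, b=(-1.0, 1.0))


class TestCollapsing:
    def test_sparse_category_merged_with_neighbor(self):
        y = np.array([0] * 50 + [1] * 2 + [2] * 50 + [3] * 50 + [4] * 50,
                     dtype=float)
        y_new, mapping = collapse_sparse_categories(y, min_count=5)
        assert mapping[1] == mapping[0]          # merged downward
        assert len(set(mapping.values())) == 4
        assert np.nanmax(y_new) == 3

    def test_no_collapse_when_all_frequent(self):
        y = np.array([0, 1, 2, 3, 4] * 20, dtype=float)
        y_new, mapping = collapse_sparse_categories(y, min_count=5)
        assert mapping == {k: k for k in range(5)}
        np.testing.assert_array_equal(y, y_new)

    def test_single_category_rejected(self):
        with pytest.raises(DataError):
            collapse_sparse_categories(np.array([2.0] * 30), min_count=5)


class TestCalibration:
    def test_parameter_recovery(self):
        """Simulate-then-refit at n=1000, 10 items recovers a and b."""
        rng = np.random.default_rng(42)
        n, J = 1000, 10
        a_true = np.linspace(1.2, 2.0, J)
        b_true = [np.linspace(-1.8, 1.8, 4) + off
                  for off in np.linspace(-0.7, 0.7, J)]
        theta = rng.normal(size=n)
        y = np.column_stack([_simulate(rng, theta, a_true[j], b_true[j])
                             for j in range(J)])
        ids = [f"i{j}" for j in range(J)]
        cal, y_c = fit_grm(y, ids)
        a_hat = np.array([cal.params[i].a for i in ids])
        b_hat = np.array([cal.params[i].b for i in ids])
        # pilot-established tolerances for this design
        assert np.mean(np.abs(a_hat - a_true)) < 0.15
        assert np.mean(np.abs(b_hat - np.array(b_true))) < 0.12
        # EM monotonicity of the marginal log-likelihood
        traj = np.array(cal.loglik_trajectory)
        assert np.all(np.diff(traj) >= -1e-6)

    def test_empty_dif_set_equals_pooled_calibration(self, null_matrix):
        ids = null_matrix.spec.item_ids
        g = null_matrix.group_indicator(("child", "parent"))
        y = null_matrix.responses()
        cal_plain, _ = fit_grm(y, ids)
        cal_empty, _ = fit_grm(y, ids, groups=g, dif_items=())
        for i in ids:
            assert cal_empty.params[i].a == pytest.approx(cal_plain.params[i].a,
                                                          abs=1e-6)
            np.testing.assert_allclose(cal_empty.params[i].b,
                                       cal_plain.params[i].b, atol=1e-6)

    def test_identical_groups_give_symmetric_group_params(self):
        """Duplicating the data into two identical groups: the two
        group-specific parameter sets agree."""
        rng = np.random.default_rng(7)
        theta = rng.normal(size=400)
        b = np.linspace(-1.5, 1.5, 4)
        y1 = np.column_stack([_simulate(rng, theta, 1.5, b + d)
                              for d in (-0.3, 0.0, 0.3)])
        y = np.vstack([y1, y1])
        g = np.r_[np.zeros(400), np.ones(400)]
        ids = ["i0", "i1", "i2"]
        cal, _ = fit_grm(y, ids, groups=g, dif_items=set(ids))
        for i in ids:
            p0, p1 = cal.params[i][0.0], cal.params[i][1.0]
            assert p0.a == pytest.approx(p1.a, abs=1e-3)
            np.testing.assert_allclose(p0.b, p1.b, atol=1e-3)

    def test_trait_scale_identification(self, null_matrix):
        ids = null_matrix.spec.item_ids
        cal, y_c = fit_grm(null_matrix.responses(), ids)
        theta, sd = eap_score(y_c, cal)
        assert abs(theta.mean()) < 0.1
        assert theta.std() < 1.05


@pytest.fixture(scope="module")
def symmetric_cal():
    rng = np.random.default_rng(3)
    theta = rng.normal(size=1500)
    b = np.array([-1.5, -0.5, 0.5, 1.5])
    y = np.column_stack([_simulate(rng, theta, 1.6, b) for _ in range(5)])
    cal, y_c = fit_grm(y, [f"i{j}" for j in range(5)])
    return cal


class TestEAP:

    def test_middle_categories_score_near_zero(self, symmetric_cal):
        pattern = np.full((1, 5), 2.0)
        theta, sd = eap_score(pattern, symmetric_cal)
        assert abs(theta[0]) < 0.15
        assert sd[0] < 1.0          # shrinkage below the prior SD

    def test_top_pattern_scores_higher(self, symmetric_cal):
        top, _ = eap_score(np.full((1, 5), 4.0), symmetric_cal)
        mid, _ = eap_score(np.full((1, 5), 2.0), symmetric_cal)
        assert top[0] > mid[0] > -4.0

    def test_matches_fine_grid_integration(self):
        """EAP for a printed 5-item pattern equals brute-force numerical
        integration on a 10x finer grid, to 3 decimals."""
        params = [GRMItemParams(f"i{j}", a, tuple(b)) for j, (a, b) in
                  enumerate([(1.7, [-2, -1, 0, 1]),
                             (1.2, [-1.5, -0.5, 0.5, 1.5]),
                             (2.1, [-1, 0, 1, 2]),
                             (0.9, [-2.5, -1, 0.5, 2]),
                             (1.5, [-0.5, 0.1, 0.9, 1.8])])]
        pattern = np.array([[3, 2, 4, 1, 2]], dtype=float)

        # oracle: dense-grid posterior integration, independent arithmetic
        grid = np.linspace(-4, 4, 481)
        dens = norm.pdf(grid)
        like = np.ones_like(grid)
        for j, p in enumerate(params):
            k = int(pattern[0, j])
            cum_hi = 1.0 if k == 0 else expit(p.a * (grid - p.b[k - 1]))
            cum_lo = 0.0 if k == len(p.b) else expit(p.a * (grid - p.b[k]))
            like *= cum_hi - cum_lo
        post = like * dens
        post /= np.trapezoid(post, grid)
        theta_oracle = np.trapezoid(grid * post, grid)

        from difagree.grm import GRMCalibration, make_quadrature

        nodes, w = make_quadrature(481, 4.0)
        cal = GRMCalibration([p.item_id for p in params],
                             {p.item_id: p for p in params}, [0.0], True, 1,
                             nodes, w)
        theta, sd = eap_score(pattern, cal)
        assert theta[0] == pytest.approx(theta_oracle, abs=1e-3)

    def test_missing_items_ignored(self, symmetric_cal):
        full = np.array([[2, 2, 2, 2, 2]], dtype=float)
        holey = np.array([[2, np.nan, 2, np.nan, 2]], dtype=float)
        t_full, sd_full = eap_score(full, symmetric_cal)
        t_holey, sd_holey = eap_score(holey, symmetric_cal)
        assert abs(t_holey[0] - t_full[0]) < 0.2
        assert sd_holey[0] > sd_full[0]      # fewer items, less information
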