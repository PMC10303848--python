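import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

import adhtraj as at
from adhtraj.gbtm import (
    GBTMParams,
    TrajectorySpec,
    _unpack,
    bic,
    fit_em,
    loglik,
    match_groups,
    posterior,
    wald_highest_terms,
)


def params_const(pi, logits):
    """Order-0 params with given per-group constant logits."""
    return GBTMParams(pi=np.asarray(pi, float),
                      beta=[np.array([l], float) for l in logits])


def brute_force_loglik(params, panel):
    """Explicit per-group product over patients; independent of the
    vectorized log-space path."""
    Y = np.asarray(panel)
    probs = params.trajectory_probs(Y.shape[1])
    total = 0.0
    for y in Y:
        mix = 0.0
        for g in range(params.G):
            f = 1.0
            for t, yt in enumerate(y):
                p = probs[g, t]
                f *= p if yt == 1 else (1 - p)
            mix += params.pi[g] * f
        total += np.log(mix)
    return total


class TestTrajectorySpec:
    def test_order_bounds(self):
        with pytest.raises(ValueError):
            TrajectorySpec(1, (6,))

    def test_orders_length(self):
        with pytest.raises(ValueError):
            TrajectorySpec(2, (1,))

    def test_n_params(self):
        assert TrajectorySpec(3, (2, 0, 1)).n_params == 2 + 3 + 1 + 2


class TestLoglik:
    def test_half_probability_hand_value(self):
        # G=1, order 0, intercept 0 -> p = 0.5; N=4, T=12 -> 48 ln(1/2)
        params = params_const([1.0], [0.0])
        panel = np.random.default_rng(0).integers(0, 2, (4, 12))
        assert loglik(params, panel) == pytest.approx(48 * np.log(0.5), abs=1e-10)

    def test_identical_components_collapse(self):
        panel = np.random.default_rng(1).integers(0, 2, (10, 12))
        one = params_const([1.0], [0.7])
        two = params_const([0.3, 0.7], [0.7, 0.7])
        assert loglik(two, panel) == pytest.approx(loglik(one, panel), abs=1e-10)

    def test_degenerate_mixture(self):
        panel = np.random.default_rng(2).integers(0, 2, (8, 12))
        mix = params_const([1.0, 0.0], [1.2, -0.4])
        solo = params_const([1.0], [1.2])
        assert loglik(mix, panel) == pytest.approx(loglik(solo, panel), abs=1e-10)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            loglik(params_const([1.0], [0.0]), np.full((2, 3), 0.5))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_on_tiny_panels(self, seed):
        rng = np.random.default_rng(seed)
        G = int(rng.integers(1, 4))
        pi = rng.dirichlet(np.ones(G))
        params = GBTMParams(pi=pi, beta=[rng.normal(0, 1, int(rng.integers(1, 3)))
                                         for _ in range(G)])
        panel = rng.integers(0, 2, (int(rng.integers(1, 13)), 3))
        assert loglik(params, panel) == pytest.approx(
            brute_force_loglik(params, panel), rel=1e-10)


class TestPosterior:
    def test_identical_components_give_pi(self):
        panel = np.random.default_rng(3).integers(0, 2, (6, 12))
        params = params_const([0.3, 0.7], [0.5, 0.5])
        post = posterior(params, panel)
        np.testing.assert_allclose(post, np.tile([0.3, 0.7], (6, 1)), atol=1e-12)

    def test_one_hot_pi(self):
        panel = np.random.default_rng(4).integers(0, 2, (5, 12))
        post = posterior(params_const([1.0, 0.0], [1.0, -1.0]), panel)
        np.testing.assert_allclose(post[:, 0], 1.0)

    def test_hand_computed_bayes(self):
        # pi=(.5,.5), p1=.9, p2=.1, single month, y=1 -> posterior (0.9, 0.1)
        params = params_const([0.5, 0.5], [logit(0.9), logit(0.1)])
        post = posterior(params, np.array([[1]]))
        np.testing.assert_allclose(post[0], [0.9, 0.1], atol=1e-12)

    def test_rows_sum_to_one(self, paper5_fit):
        np.testing.assert_allclose(paper5_fit.posteriors.sum(axis=1), 1.0,
                                   atol=1e-10)


class TestFitEm:
    def test_single_group_order0_closed_form(self):
        rng = np.random.default_rng(5)
        panel = (rng.random((200, 12)) < 0.75).astype(int)
        frac = panel.mean()
        fit = fit_em(panel, TrajectorySpec(1, (0,)), starts=1, seed=0)
        assert fit.params.beta[0][0] == pytest.approx(logit(frac), abs=1e-6)
        assert fit.params.pi[0] == 1.0

    def test_two_group_easy_recovery(self):
        scen = at.default_scenario("two_group_easy", n_patients=1000, seed=8)
        cohort = at.simulate_panel(scen)
        fit = fit_em(cohort.panel, TrajectorySpec.common(2, 0), starts=5, seed=0)
        perm = match_groups(fit.params.trajectory_probs(12),
                            scen.trajectory_probs())
        pi = fit.params.pi[perm]
        se = np.sqrt(0.6 * 0.4 / 1000)
        assert abs(pi[0] - 0.6) < 3 * se
        intercepts = np.array([fit.params.beta[g][0] for g in perm])
        assert abs(intercepts[0] - 3.0) < 0.5
        assert abs(intercepts[1] + 3.0) < 0.5

    def test_label_switching_leaves_loglik_invariant(self):
        panel = np.random.default_rng(6).integers(0, 2, (30, 12))
        a = params_const([0.3, 0.7], [1.0, -1.0])
        b = params_const([0.7, 0.3], [-1.0, 1.0])
        assert loglik(a, panel) == pytest.approx(loglik(b, panel), abs=1e-10)

    def test_determinism(self, paper5_cohort):
        f1 = fit_em(paper5_cohort.panel[:200], TrajectorySpec.common(2, 1),
                    starts=3, seed=4)
        f2 = fit_em(paper5_cohort.panel[:200], TrajectorySpec.common(2, 1),
                    starts=3, seed=4)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.posteriors, f2.posteriors)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.empty((0, 12)), TrajectorySpec(1, (0,)))

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.ones((1, 12), dtype=int), TrajectorySpec.common(2, 0))

    def test_paper5_share_recovery(self, paper5_scenario, paper5_cohort,
                                   paper5_fit):
        perm = match_groups(paper5_fit.params.trajectory_probs(12),
                            paper5_scenario.trajectory_probs())
        pi = paper5_fit.params.pi[perm]
        truth = np.asarray(paper5_scenario.group_probs)
        assert (np.abs(pi - truth) < 0.03).all()


class TestBic:
    def test_hand_value(self):
        panel = np.random.default_rng(0).integers(0, 2, (4, 12))
        params = params_const([1.0], [0.0])
        ll = loglik(params, panel)
        fit = fit_em(panel, TrajectorySpec(1, (0,)), starts=1, seed=0)
        # k = 1 free parameter; N = 4 patients
        assert bic(fit) == pytest.approx(fit.loglik - 0.5 * np.log(4))
        assert 48 * np.log(0.5) - 0.5 * np.log(4) == pytest.approx(
            ll - 0.5 * np.log(4))

    def test_penalty_monotone_in_k(self):
        panel = np.random.default_rng(7).integers(0, 2, (50, 12))
        f0 = fit_em(panel, TrajectorySpec(1, (0,)), starts=1, seed=0)
        f1 = fit_em(panel, TrajectorySpec(1, (1,)), starts=1, seed=0)
        # higher order can only raise logL, but pays ln N / 2 per parameter
        assert f1.loglik >= f0.loglik - 1e-8
        penalty = 0.5 * np.log(50)
        assert f1.bic <= f1.loglik - 2 * penalty + 1e-8

    def test_observation_convention_differs(self, paper5_fit):
        assert bic(paper5_fit, "observations") < bic(paper5_fit, "patients")

    def test_relabeling_leaves_bic_unchanged(self):
        panel = np.random.default_rng(8).integers(0, 2, (40, 12))
        fit = fit_em(panel, TrajectorySpec.common(2, 0), starts=3, seed=0)
        flipped = GBTMParams(pi=fit.params.pi[::-1].copy(),
                             beta=list(fit.params.beta[::-1]))
        assert loglik(flipped, panel) == pytest.approx(fit.loglik, abs=1e-8)


class TestWald:
    def test_zero_coefficient_p_one(self):
        # an order-1 group whose slope is truly zero: p not significant
        rng = np.random.default_rng(9)
        panel = (rng.random((400, 12)) < 0.6).astype(int)
        fit = fit_em(panel, TrajectorySpec(1, (1,)), starts=1, seed=0)
        tests = wald_highest_terms(fit, panel)
        assert tests[0]["p"] > 0.05

    def test_z_to_p_mapping(self):
        from scipy import stats
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_order0_group_tests_intercept(self):
        rng = np.random.default_rng(10)
        panel = (rng.random((300, 12)) < 0.9).astype(int)
        fit = fit_em(panel, TrajectorySpec(1, (0,)), starts=1, seed=0)
        tests = wald_highest_terms(fit, panel)
        assert tests[0]["order"] == 0
        assert tests[0]["coef"] == pytest.approx(fit.params.beta[0][0])
        assert tests[0]["p"] < 1e-6  # strongly nonzero intercept

    def test_strong_slope_significant(self):
        scen = at.Scenario(n_patients=500, group_probs=(1.0,),
                           group_trajectories=((0.0, 2.0),), seed=12)
        cohort = at.simulate_panel(scen)
        fit = fit_em(cohort.panel, TrajectorySpec(1, (1,)), starts=1, seed=0)
        tests = wald_highest_terms(fit, cohort.panel)
        assert tests[0]["p"] < 1e-6


class TestEmMonotonicity:
    def test_no_decrease_warning_on_paper5_subset(self, paper5_cohort,
                                                  recwarn):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            fit_em(paper5_cohort.panel[:300], TrajectorySpec.common(3, 2),
                   starts=3, seed=1)


def test_unpack_pack_round_trip():
    params = GBTMParams(pi=np.array([0.2, 0.5, 0.3]),
                        beta=[np.array([1.0]), np.array([0.5, -0.2]),
                              np.array([0.1, 0.2, 0.3])])
    from adhtraj.gbtm import _pack
    rebuilt = _unpack(_pack(params), params.spec)
    np.testing.assert_allclose(rebuilt.pi, params.pi, atol=1e-12)
    for a, b in zip(rebuilt.beta, params.beta):
        np.testing.assert_allclose(a, b)


def test_match_groups_permutation():
    ref = np.array([[0.9] * 12, [0.1] * 12, [0.5] * 12])
    fitted = ref[[2, 0, 1]]
    perm = match_groups(fitted, ref)
    np.testing.assert_array_equal(perm, [1, 2, 0])
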