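"""MRF prior, conditionals, covariates, and the estimation loop."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq, minimize
from scipy.special import expit, log_expit

from netdnv import (
    CountParams,
    GeneNetwork,
    GeneTable,
    MrfParams,
    SimConfig,
    ThetaFitError,
    compute_covariates,
    conditional_prob,
    conditional_probs,
    estimate_gamma,
    fit,
    fit_theta0,
    icm_update,
    log_prior_unnormalized,
    pclk,
    simulate_replicate,
)
from netdnv.dnv_data import log_emission_pair

from conftest import (
    enumerate_conditional,
    joint_log_weight,
    make_table,
    random_mrf_params,
    random_network,
)


class TestLogPrior:
    def test_all_null_with_zero_tau0_vanishes(self, path3_net):
        S = -np.ones(3, dtype=int)
        p = MrfParams(h=-2.0, tau0=0.0, tau1=0.7)
        assert log_prior_unnormalized(S, path3_net, p) == 0.0

    def test_single_edge_direct_sum(self):
        net = GeneNetwork.from_edges(["A", "B"], [("A", "B")])
        S = np.array([1, 1])
        p = MrfParams(h=-1.0, tau0=0.0, tau1=0.5)
        # h*2 + tau1*(w_A + w_B) = -2 + 0.5*2
        assert log_prior_unnormalized(S, net, p) == pytest.approx(-1.0)

    def test_matches_term_by_term_oracle(self, path3_net):
        rng = np.random.default_rng(7)
        for _ in range(50):
            S = rng.choice([-1, 1], size=3)
            p = random_mrf_params(rng)
            assert log_prior_unnormalized(S, path3_net, p) == pytest.approx(
                joint_log_weight(S, path3_net, p), rel=1e-12
            )

    def test_misaligned_length_errors(self, path3_net):
        with pytest.raises(ValueError):
            log_prior_unnormalized(np.array([1, -1]), path3_net, MrfParams(0, 0, 0))


class TestConditional:
    def test_isolated_gene_marginal(self):
        net = GeneNetwork.from_edges(["A"], [])
        p = conditional_prob(0, np.array([-1]), net, MrfParams(h=-4.0, tau0=0.3, tau1=0.3))
        assert p == pytest.approx(math.exp(-4) / (1 + math.exp(-4)), abs=1e-9)
        assert p == pytest.approx(0.017986, abs=1e-6)

    def test_zero_taus_give_sigmoid_h_everywhere(self, star_net):
        rng = np.random.default_rng(0)
        S = rng.choice([-1, 1], size=5)
        probs = conditional_probs(S, star_net, MrfParams(h=-1.3, tau0=0.0, tau1=0.0))
        assert np.allclose(probs, expit(-1.3))

    def test_matches_joint_enumeration_small_networks(self):
        """Conditional from the logistic form equals the conditional obtained
        by normalizing the joint Gibbs measure over S_i."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            net = random_network(rng, 2, 4)
            S = rng.choice([-1, 1], size=net.n_nodes)
            params = random_mrf_params(rng)
            i = int(rng.integers(net.n_nodes))
            assert conditional_prob(i, S, net, params) == pytest.approx(
                enumerate_conditional(i, S, net, params), abs=1e-10
            )


class TestCovariates:
    def test_star_all_leaves_plus(self, star_net):
        S = np.array([-1, 1, 1, 1, 1])  # nodes sorted: C, L1..L4
        x1, x0 = compute_covariates(S, star_net)
        i = star_net.node_index["C"]
        assert x1[i] == pytest.approx(2 * 4 + 4 * 1)
        assert x0[i] == 0.0

    def test_star_all_leaves_minus(self, star_net):
        S = -np.ones(5, dtype=int)
        x1, x0 = compute_covariates(S, star_net)
        i = star_net.node_index["C"]
        assert x1[i] == 0.0
        assert x0[i] == pytest.approx(12.0)

    def test_sum_identity_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_network(rng, 3, 12)
            S = rng.choice([-1, 1], size=net.n_nodes)
            x1, x0 = compute_covariates(S, net)
            for i, g in enumerate(net.nodes):
                nbrs = [net.node_index[b] for b in net.neighbors(g)]
                expected = net.weights[i] * len(nbrs) + sum(net.weights[k] for k in nbrs)
                assert x1[i] + x0[i] == pytest.approx(expected, rel=1e-12)

    def test_isolated_gene_zero(self):
        net = GeneNetwork.from_edges(["A", "B", "C"], [("A", "B")])
        x1, x0 = compute_covariates(np.array([1, 1, 1]), net)
        i = net.node_index["C"]
        assert x1[i] == 0.0 and x0[i] == 0.0


class TestFitTheta0:
    def test_intercept_only_recovers_logit(self):
        net = GeneNetwork.from_edges([f"g{i}" for i in range(10)], [])
        S = np.array([1, 1, 1, -1, -1, -1, -1, -1, -1, -1])
        params = fit_theta0(S, net, ridge_lambda=0.0)
        assert params.h == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)
        assert params.tau0 == 0.0 and params.tau1 == 0.0

    def test_ridge_keeps_all_null_finite(self):
        net = GeneNetwork.from_edges([f"g{i}" for i in range(8)], [])
        S = -np.ones(8, dtype=int)
        params = fit_theta0(S, net, ridge_lambda=0.5)
        assert np.isfinite(params.h) and params.h < 0

    def test_separable_unpenalized_raises(self):
        net = GeneNetwork.from_edges(["A", "B", "C", "D"], [("A", "B"), ("C", "D")])
        with pytest.raises(ThetaFitError) as exc:
            fit_theta0(-np.ones(4, dtype=int), net, ridge_lambda=0.0)
        assert exc.value.last_params is not None

    @pytest.mark.parametrize("lam", [0.0, 0.01, 0.1, 1.0])
    def test_matches_independent_optimizer(self, lam):
        """Newton solution equals a generic quasi-Newton optimizer of the same
        penalized pseudo-likelihood."""
        rng = np.random.default_rng(11)
        net = random_network(rng, 10, 12, p_edge=0.5)
        n = net.n_nodes
        S = rng.choice([-1, 1], size=n, p=[0.6, 0.4])
        x1, x0 = compute_covariates(S, net)
        y = (S == 1).astype(float)
        sgn = np.where(y == 1, 1.0, -1.0)
        X = np.column_stack([np.ones(n), x1, -x0])

        def negobj(t):
            return -(log_expit(sgn * (X @ t)).sum() - lam * (t @ t))

        def neggrad(t):
            p = expit(X @ t)
            return -(X.T @ (y - p) - 2 * lam * t)

        ref = minimize(negobj, np.zeros(3), jac=neggrad, method="BFGS", tol=1e-12)
        ours = fit_theta0(S, net, ridge_lambda=lam, nonneg=False)
        assert ours.h == pytest.approx(ref.x[0], abs=1e-6)
        assert ours.tau1 == pytest.approx(ref.x[1], abs=1e-6)
        assert ours.tau0 == pytest.approx(ref.x[2], abs=1e-6)

    def test_nonneg_floors_taus(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            net = random_network(rng, 6, 10, p_edge=0.5)
            S = rng.choice([-1, 1], size=net.n_nodes)
            params = fit_theta0(S, net, ridge_lambda=0.1, nonneg=True)
            assert params.tau0 >= 0.0 and params.tau1 >= 0.0


def _icm_reference(S, net, params, counts, table):
    """Independent step-by-step evaluation of the ICM objective."""
    S = np.array(S)
    le_minus, le_plus = log_emission_pair(table, counts.gamma)
    index = net.node_index
    for i, g in enumerate(net.nodes):
        scores = {}
        for cand in (1, -1):
            trial = S.copy()
            trial[i] = cand
            le = le_plus[i] if cand == 1 else le_minus[i]
            total = le + math.log(
                conditional_prob(i, trial, net, params)
                if cand == 1
                else 1 - conditional_prob(i, trial, net, params)
            )
            for b in net.neighbors(g):
                k = index[b]
                pk = conditional_prob(k, trial, net, params)
                total += math.log(pk if trial[k] == 1 else 1 - pk)
            scores[cand] = total
        S[i] = 1 if scores[1] > scores[-1] else -1
    return S


class TestIcm:
    def test_degenerate_prior_dominates(self, path3_net):
        table = make_table(path3_net, [2, 0, 1], [1e-6] * 3, 1000)
        params = MrfParams(h=-2.0, tau0=0.0, tau1=0.0)
        out = icm_update(np.array([1, 1, 1]), path3_net, params, CountParams(1.0), table)
        assert np.all(out == -1)

    def test_isolated_gene_flip_boundary(self):
        """Closed-form threshold: an isolated gene flips to +1 exactly when
        the log emission difference exceeds -h."""
        net = GeneNetwork.from_edges(["A"], [])
        mu, n_trios, gamma, h = 1e-5, 5000, math.exp(3), -4.0
        rate0 = 2 * n_trios * mu
        y_threshold = (rate0 * (gamma - 1) - h) / math.log(gamma)
        y_lo, y_hi = int(math.floor(y_threshold)), int(math.ceil(y_threshold))
        params = MrfParams(h=h, tau0=0.0, tau1=0.0)
        for y, expected in ((y_lo, -1), (y_hi, 1)):
            table = make_table(net, [y], [mu], n_trios)
            out = icm_update(np.array([-1]), net, params, CountParams(gamma), table)
            assert out[0] == expected

    def test_matches_stepwise_oracle(self, path3_net):
        rng = np.random.default_rng(21)
        for _ in range(30):
            S0 = rng.choice([-1, 1], size=3)
            params = random_mrf_params(rng, h_range=(-3, 1), tau_range=(0, 1))
            gamma = float(np.exp(rng.uniform(0.5, 3)))
            table = make_table(
                path3_net,
                rng.integers(0, 5, size=3),
                10 ** rng.uniform(-6.5, -5, 3),
                2000,
            )
            ours = icm_update(S0, path3_net, params, CountParams(gamma), table)
            ref = _icm_reference(S0, path3_net, params, CountParams(gamma), table)
            assert np.array_equal(ours, ref)


class TestEstimateGamma:
    def test_closed_form_arithmetic(self):
        table = make_table(["a", "b", "c"], [2, 1, 0], [1e-6, 2e-6, 1e-6], 1000)
        params, degenerate = estimate_gamma(np.array([1, 1, 1]), table)
        assert not degenerate
        assert params.gamma == pytest.approx(3 / (2 * 1000 * 4e-6))
        assert params.gamma == pytest.approx(375.0)

    def test_zero_counts_clip_to_one(self):
        table = make_table(["a", "b"], [0, 0], [1e-6, 1e-6], 1000)
        params, degenerate = estimate_gamma(np.array([1, 1]), table)
        assert params.gamma == 1.0 and not degenerate

    def test_no_risk_gene_returns_fallback(self):
        table = make_table(["a"], [3], [1e-6], 1000)
        params, degenerate = estimate_gamma(np.array([-1]), table, fallback_gamma=7.0)
        assert degenerate and params.gamma == 7.0

    def test_matches_numeric_maximizer(self):
        """Closed form equals the 1-D maximizer of the risk-gene Poisson
        log likelihood sum_{S_i=1} (-2*N*mu_i*g + Y_i*log g), located
        independently as the root of its score function."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 20
            mu = 10 ** rng.uniform(-7, -5, n)
            y = rng.poisson(2 * 5000 * mu * 30)
            S = np.where(rng.random(n) < 0.5, 1, -1)
            if not np.any((S == 1) & (y > 0)):
                continue
            table = make_table([f"g{i:02d}" for i in range(n)], y, mu, 5000)
            mask = S == 1

            def score(g, mask=mask, y=y, mu=mu):
                return float(-np.sum(2 * 5000 * mu[mask]) + np.sum(y[mask]) / g)

            ref = brentq(score, 1e-9, 1e6, xtol=1e-12, rtol=1e-14)
            params, _ = estimate_gamma(S, table)
            assert params.gamma == pytest.approx(max(1.0, ref), abs=1e-8)


@pytest.fixture(scope="module")
def small_replicate():
    cfg = SimConfig(n_genes=300, tau1=0.5, n_trios=5000, beta=3.5, seed=77,
                    prior_n_iter=2000, prior_n_burnin=1000)
    return simulate_replicate(cfg, 0)


class TestFit:
    def test_no_network_collapses_to_mixture(self, small_replicate):
        rep = small_replicate
        net = rep.net.with_zero_weights()
        res = fit(rep.table, net)
        # with all weights zero the taus never enter the likelihood
        assert res.params.tau0 == 0.0 and res.params.tau1 == 0.0
        frac = np.mean(res.states == 1)
        assert res.params.h == pytest.approx(math.log(frac / (1 - frac)), abs=0.2)

    def test_zero_tau_fit_invariant_to_edges(self, small_replicate):
        """With tau0 = tau1 fixed at zero the fit ignores the edge structure."""
        rep = small_replicate
        res_a = fit(rep.table, rep.net, fix_tau0=0.0, fix_tau1=0.0)
        shuffled = GeneNetwork.from_edges(
            rep.net.nodes,
            [(rep.net.nodes[0], g) for g in rep.net.nodes[1:50]],
        )
        res_b = fit(rep.table, shuffled, fix_tau0=0.0, fix_tau1=0.0)
        assert np.array_equal(res_a.states, res_b.states)
        assert res_a.params.h == pytest.approx(res_b.params.h, abs=1e-9)
        assert res_a.counts.gamma == pytest.approx(res_b.counts.gamma, rel=1e-12)

    def test_pclk_trace_nondecreasing(self, small_replicate):
        rep = small_replicate
        res = fit(rep.table, rep.net)
        trace = res.pclk_trace
        assert trace.size >= 1
        # tolerate tol-level wiggle from the parameter refits between sweeps
        slack = 1e-4 * np.abs(trace).max() + 1e-9
        assert np.all(np.diff(trace) >= -slack)

    def test_misaligned_inputs_error(self, small_replicate):
        rep = small_replicate
        net = GeneNetwork.from_edges(["x", "y"], [("x", "y")])
        with pytest.raises(ValueError):
            fit(rep.table, net)

    def test_seed_init_and_convergence_flags(self, small_replicate):
        rep = small_replicate
        seeds = [g for g, s in zip(rep.table.genes, rep.s_true) if s == 1]
        res = fit(rep.table, rep.net, init="seeds", init_seeds=seeds)
        assert res.converged
        assert res.pclk_trace.size == res.n_iter
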