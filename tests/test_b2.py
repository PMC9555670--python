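import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from conftest import make_network
from proxnet.b2 import (
    B2Model,
    B2Results,
    B2Spec,
    fit_b2,
    logistic_mle_oracle,
    summarize_or,
)
from proxnet.synthetic import B2Truth, simulate_b2_network


def dummy_halves(n):
    X = np.zeros((n, 1))
    X[n // 2:, 0] = 1.0
    return X


def simulated_network(truth, n, seed, X=None):
    X = np.zeros((n, 0)) if X is None else X
    adj, _ = simulate_b2_network(truth, X, n, seed=seed)
    names = [f"x{k}" for k in range(X.shape[1])]
    return make_network(adj, X if X.size else None, names)


SMALL_SPEC = B2Spec(n_chains=2, n_burnin=400, n_iter=1200, seed=99)


class TestLogisticMLEOracle:
    def test_intercept_only_recovers_logit_density(self, rng):
        adj = np.zeros((20, 20), dtype=bool)
        iu = np.triu_indices(20, 1)
        edges = rng.uniform(size=len(iu[0])) < 0.3
        adj[iu] = edges
        adj |= adj.T
        net = make_network(adj)
        mle = logistic_mle_oracle(net)
        assert mle.converged
        assert mle.mu == pytest.approx(logit(edges.mean()), abs=1e-6)

    def test_density_half_gives_zero_intercept(self):
        adj = np.array([[0, 1, 0, 0], [1, 0, 0, 1], [0, 0, 0, 1], [0, 1, 1, 0]], dtype=bool)
        net = make_network(adj)  # 3 edges of 6 dyads
        assert logistic_mle_oracle(net).mu == pytest.approx(0.0, abs=1e-8)

    def test_perfect_separation_flagged(self):
        # edges exactly where the dummy pair-sum is 2: separation
        n = 8
        X = dummy_halves(n)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(4, n):
            for j in range(i + 1, n):
                adj[i, j] = adj[j, i] = True
        net = make_network(adj, X, ["d"])
        with pytest.warns(UserWarning, match="converge"):
            mle = logistic_mle_oracle(net)
        assert not mle.converged


class TestFitB2:
    def test_posterior_matches_mle_when_sigma_pinned_at_zero(self):
        net = simulated_network(B2Truth(mu=-1.0, gamma=(0.4,)), 60, seed=5,
                                X=dummy_halves(60))
        mle = logistic_mle_oracle(net)
        spec = B2Spec(n_chains=2, n_burnin=500, n_iter=1500, seed=1, fix_sigma_a=0.0)
        res = B2Model(net, spec).fit()
        assert res.posterior_mean("mu") == pytest.approx(mle.mu, abs=0.05)
        assert res.posterior_mean("x0") == pytest.approx(mle.gamma[0], abs=0.05)

    def test_empty_network_warns_and_or_ci_contains_one(self):
        net = make_network(np.zeros((12, 12), dtype=bool), dummy_halves(12), ["d"])
        with pytest.warns(UserWarning, match="weakly identified"):
            model = B2Model(net, B2Spec(n_chains=2, n_burnin=300, n_iter=800, seed=3))
        res = model.fit()
        # density intercept pushed far negative, below logit(1 / n_dyads)
        assert res.posterior_mean("mu") < logit(1.0 / net.n_eligible_dyads)
        or_sum = res.summarize_or("d")
        assert or_sum.ci_low <= 1.0 <= or_sum.ci_high

    def test_same_seed_reproduces_draws_exactly(self):
        net = simulated_network(B2Truth(mu=-1.5, sigma_a=0.4), 30, seed=8)
        spec = B2Spec(n_chains=2, n_burnin=200, n_iter=400, seed=42)
        a, b = B2Model(net, spec).fit(), B2Model(net, spec).fit()
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.sigma_a, b.sigma_a)

    def test_actor_relabelling_leaves_mle_invariant(self):
        net = simulated_network(B2Truth(mu=-1.0, gamma=(0.3,)), 24, seed=2,
                                X=dummy_halves(24))
        perm = np.random.default_rng(0).permutation(24)
        relabelled = make_network(
            net.adjacency[np.ix_(perm, perm)],
            net.covariates.to_numpy()[perm],
            ["x0"],
        )
        a, b = logistic_mle_oracle(net), logistic_mle_oracle(relabelled)
        assert a.mu == pytest.approx(b.mu, abs=1e-6)
        assert a.gamma[0] == pytest.approx(b.gamma[0], abs=1e-6)

    def test_structural_zeros_do_not_enter_likelihood(self):
        # the ineligible block is all non-edges; excluding it must raise the
        # estimated density relative to coding it as observed zeros
        n = 10
        adj = np.zeros((n, n), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        mask = np.zeros((n, n), dtype=bool)
        mask[:5, :5] = ~np.eye(5, dtype=bool)
        masked = make_network(adj, dyad_mask=mask)
        full = make_network(adj)
        assert logistic_mle_oracle(masked).mu > logistic_mle_oracle(full).mu
        assert masked.n_eligible_dyads == 10

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            B2Model(make_network(np.zeros((1, 1), dtype=bool)))
        bad_cov = np.full((4, 1), np.nan)
        with pytest.raises(ValueError, match="finite"):
            B2Model(make_network(np.zeros((4, 4), dtype=bool), bad_cov, ["x"]))

    def test_fit_b2_wrapper_equivalent(self):
        net = simulated_network(B2Truth(mu=-1.0), 16, seed=4)
        spec = B2Spec(n_chains=1, n_burnin=100, n_iter=200, seed=5)
        assert np.array_equal(fit_b2(net, spec).mu, B2Model(net, spec).fit().mu)


def results_from_draws(gamma_draws, name="d"):
    """B2Results stub around given gamma draws (chains x draws)."""
    net = make_network(np.zeros((4, 4), dtype=bool), np.zeros((4, 1)), [name])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = B2Model(net, B2Spec(n_chains=gamma_draws.shape[0], n_burnin=1, n_iter=1))
    g = np.asarray(gamma_draws, dtype=float)[:, :, None]
    zeros = np.zeros(g.shape[:2])
    return B2Results(model, mu=zeros, gamma=g, sigma_a=zeros + 0.1,
                     actor_effects=None, acceptance={})


class TestORSummary:
    def test_degenerate_posterior_at_zero(self):
        res = results_from_draws(np.zeros((2, 100)))
        s = res.summarize_or("d")
        assert (s.or_point, s.ci_low, s.ci_high) == (1.0, 1.0, 1.0)

    def test_constant_log_two(self):
        res = results_from_draws(np.full((2, 50), np.log(2.0)))
        assert res.summarize_or("d").or_point == pytest.approx(2.0)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(0.0, 0.1, size=(2, 20000))
        s = summarize_or(results_from_draws(draws), "d")
        assert s.or_point == pytest.approx(np.exp(0.005), abs=0.01)
        assert s.ci_low == pytest.approx(np.exp(-0.196), abs=0.02)
        assert s.ci_high == pytest.approx(np.exp(0.196), abs=0.02)

    def test_reporting_style(self):
        res = results_from_draws(np.full((1, 10), np.log(0.83)))
        assert "OR = 0.83" in str(res.summarize_or("d"))

    def test_unknown_covariate(self):
        with pytest.raises(KeyError):
            results_from_draws(np.zeros((1, 10))).summarize_or("nope")


class TestDiagnostics:
    def test_identical_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(4, 500))
        res = results_from_draws(draws)
        diag = res.diagnostics().set_index("parameter")
        assert diag.loc["gamma[d]", "rhat"] == pytest.approx(1.0, abs=0.02)
        assert diag.loc["gamma[d]", "ess"] > 500

    def test_disjoint_chains_give_large_rhat(self):
        rng = np.random.default_rng(1)
        draws = np.stack([rng.normal(-5, 1, 300), rng.normal(5, 1, 300)])
        res = results_from_draws(draws)
        diag = res.diagnostics().set_index("parameter")
        assert diag.loc["gamma[d]", "rhat"] > 1.1

    def test_single_chain_rhat_unavailable_ess_present(self):
        res = results_from_draws(np.random.default_rng(2).normal(size=(1, 300)))
        diag = res.diagnostics().set_index("parameter")
        assert np.isnan(diag.loc["gamma[d]", "rhat"])
        assert diag.loc["gamma[d]", "ess"] > 0

    def test_summary_mentions_or_and_counts(self):
        res = results_from_draws(np.random.default_rng(3).normal(size=(2, 200)))
        text = res.summary()
        assert "OR =" in text and "eligible dyads" in text

    def test_draws_frame_long_format(self):
        res = results_from_draws(np.zeros((2, 5)))
        frame = res.to_frame()
        assert set(frame.columns) == {"chain", "iter", "parameter", "value"}
        assert len(frame) == 3 * 2 * 5  # mu, sigma_a, gamma[d]
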