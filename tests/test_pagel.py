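"""Correlated evolution of paired binary traits: rate matrices, likelihood,
ML and Bayesian fitting, stepping-stone evidence, Bayes factors."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phylocare import build_rate_matrix, log_bayes_factor, mcmc_sample, ml_fit, paired_loglik
from phylocare.mk import MkModel, mk_loglik
from phylocare.pagel import (
    PagelChain,
    SteppingStoneResult,
    bf_band,
    paired_tip_partials,
    stepping_stone_evidence,
    stepping_stone_ml,
    transition_summary,
)
from phylocare.simulate import simulate_paired_ctmc, simulate_yule_tree

from oracles import enum_loglik


class TestRateMatrix:
    def test_independent_entries(self):
        rm = build_rate_matrix("independent", dict(qA01=0.3, qA10=0.7, qB01=1.1, qB10=1.9))
        Q = rm.Q
        assert Q[0, 2] == 0.3  # 1->3: A gain at B=0
        assert Q[0, 1] == 1.1  # 1->2: B gain at A=0
        assert Q[1, 3] == 0.3  # 2->4: A gain at B=1
        assert Q[2, 3] == 1.1  # 3->4: B gain at A=1
        assert Q[0, 3] == 0.0  # dual transitions forbidden

    def test_dual_transitions_always_zero(self):
        rng = np.random.default_rng(0)
        rm = build_rate_matrix("dependent", rng.uniform(0.1, 5, 8))
        for i, j in [(0, 3), (3, 0), (1, 2), (2, 1)]:
            assert rm.Q[i, j] == 0.0

    def test_rows_sum_to_zero(self):
        rm = build_rate_matrix("constrained", dict(shared=0.5, q13=1, q31=2, q24=3, q42=4))
        assert np.allclose(rm.Q.sum(axis=1), 0.0)

    def test_dependent_all_equal_matches_independent(self):
        r = 0.8
        dep = build_rate_matrix("dependent", [r] * 8)
        ind = build_rate_matrix("independent", [r] * 4)
        assert np.allclose(dep.Q, ind.Q)

    def test_constrained_shares_b_rates(self):
        rm = build_rate_matrix("constrained", dict(shared=0.9, q13=1, q31=2, q24=3, q42=4))
        assert rm.Q[2, 3] == rm.Q[3, 2] == rm.Q[0, 1] == rm.Q[1, 0] == 0.9
        assert len(rm.rates) == 5

    def test_wrong_arity_and_negative_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix("independent", [1, 2, 3])
        with pytest.raises(ValueError):
            build_rate_matrix("dependent", [-1] + [1] * 7)
        with pytest.raises(ValueError):
            build_rate_matrix("mystery", [1, 2, 3, 4])

    def test_independent_embedding_in_dependent(self):
        ind = build_rate_matrix("independent", dict(qA01=1, qA10=2, qB01=3, qB10=4))
        dep = build_rate_matrix(
            "dependent",
            dict(q13=1, q24=1, q31=2, q42=2, q12=3, q34=3, q21=4, q43=4),
        )
        assert np.allclose(ind.Q, dep.Q)


class TestPairedLikelihood:
    def test_zero_rates_uniform_root(self, tree4):
        Q = build_rate_matrix("dependent", np.zeros(8))
        ll = paired_loglik(tree4, np.zeros(4), np.zeros(4), Q)
        assert ll == pytest.approx(np.log(0.25))

    @pytest.mark.parametrize("seed", range(4))
    def test_independent_model_factorizes(self, tree5, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.1, 3, 4)
        A = rng.integers(0, 2, 5).astype(float)
        B = rng.integers(0, 2, 5).astype(float)
        if seed % 2:
            A[0] = np.nan
        Q = build_rate_matrix("independent", r)
        ll4 = paired_loglik(tree5, A, B, Q)
        llA = _binary_loglik(tree5, A, r[0], r[1])
        llB = _binary_loglik(tree5, B, r[2], r[3])
        assert abs(ll4 - (llA + llB)) < 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, tree4, seed):
        rng = np.random.default_rng(50 + seed)
        Q = build_rate_matrix("dependent", rng.uniform(0.1, 4, 8))
        A = rng.integers(0, 2, 4).astype(float)
        B = rng.integers(0, 2, 4).astype(float)
        ll = paired_loglik(tree4, A, B, Q)
        tp = paired_tip_partials(A, B)
        oracle = enum_loglik(tree4, Q.Q, tp, np.full(4, 0.25))
        assert abs(ll - oracle) < 1e-10

    def test_relabeling_invariance(self, tree5):
        # flipping trait A's 0/1 with the matching rate swap leaves lnL unchanged
        rng = np.random.default_rng(9)
        rates = dict(zip(["q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43"], rng.uniform(0.2, 2, 8)))
        A = rng.integers(0, 2, 5).astype(float)
        B = rng.integers(0, 2, 5).astype(float)
        ll1 = paired_loglik(tree5, A, B, build_rate_matrix("dependent", rates))
        flipped = {
            "q12": rates["q34"], "q34": rates["q12"],
            "q21": rates["q43"], "q43": rates["q21"],
            "q13": rates["q31"], "q31": rates["q13"],
            "q24": rates["q42"], "q42": rates["q24"],
        }
        ll2 = paired_loglik(tree5, 1 - A, B, build_rate_matrix("dependent", flipped))
        assert abs(ll1 - ll2) < 1e-9

    def test_missing_component_marginalised(self):
        tp = paired_tip_partials(np.array([np.nan]), np.array([1.0]))
        assert np.array_equal(tp[0], [0, 1, 0, 1])

    def test_invalid_generator_rejected(self, tree4):
        with pytest.raises(ValueError):
            paired_loglik(tree4, np.zeros(4), np.zeros(4), np.ones((4, 4)))


def _binary_loglik(tree, x, q01, q10):
    from phylocare.mk import prune_loglik, tip_partials_from_states
    from scipy.linalg import expm

    Q = np.array([[-q01, q01], [q10, -q10]])
    P = np.stack([expm(Q * t) for t in tree.lengths])
    tp = tip_partials_from_states(x, 2)
    return prune_loglik(tree, P, tp, np.array([0.5, 0.5]))


class TestMlFit:
    def test_nesting_of_maximised_likelihoods(self, yule200):
        Q = build_rate_matrix(
            "constrained", dict(shared=1.0, q13=1.0, q31=1.5, q24=17.0, q42=2.7)
        )
        A, B = simulate_paired_ctmc(yule200, Q, 1, seed=51)
        fits = {
            m: ml_fit(yule200, A, B, m, n_starts=3, seed=1)
            for m in ("independent", "constrained", "dependent")
        }
        assert fits["dependent"].loglik >= fits["constrained"].loglik - 1e-6
        assert fits["constrained"].loglik >= fits["independent"].loglik - 1e-6

    def test_monomorphic_trait_flagged(self, yule100):
        rng = np.random.default_rng(2)
        A = rng.integers(0, 2, 100).astype(float)
        B = np.zeros(100)
        fit = ml_fit(yule100, A, B, "independent", n_starts=2, seed=0)
        assert fit.boundary

    def test_too_few_observations_rejected(self, tree4):
        with pytest.raises(ValueError, match="fewer than 2"):
            ml_fit(tree4, np.array([0, np.nan, np.nan, np.nan]), np.zeros(4), "independent")


class TestMcmc:
    def test_same_seed_identical_traces(self, yule100):
        Q = build_rate_matrix("independent", [1.0, 1.0, 0.8, 0.8])
        A, B = simulate_paired_ctmc(yule100, Q, 1, seed=3)
        c1 = mcmc_sample(yule100, A, B, "independent", n_iter=300, seed=11)
        c2 = mcmc_sample(yule100, A, B, "independent", n_iter=300, seed=11)
        assert np.array_equal(c1.samples, c2.samples)

    def test_posterior_interval_coverage(self):
        """Central 95% posterior intervals cover the generating rates in most
        replicates (calibration at reduced scale)."""
        truth = dict(qA01=1.0, qA10=1.2, qB01=0.8, qB10=1.0)
        Q = build_rate_matrix("independent", truth)
        hits = total = 0
        for rep in range(6):
            tree = simulate_yule_tree(150, seed=500 + rep, height=1.0)
            A, B = simulate_paired_ctmc(tree, Q, 1, seed=600 + rep)
            chain = mcmc_sample(tree, A, B, "independent", n_iter=2500, seed=rep)
            lo = np.percentile(chain.samples, 2.5, axis=0)
            hi = np.percentile(chain.samples, 97.5, axis=0)
            for j, name in enumerate(chain.param_names):
                total += 1
                hits += lo[j] <= truth[name] <= hi[j]
        assert hits / total >= 0.85

    def test_prior_only_sampling_recovers_prior_mean(self, yule100):
        import arviz as az

        A = np.zeros(100)
        B = np.ones(100)
        chain = mcmc_sample(
            yule100, A, B, "independent", n_iter=6000, seed=5, likelihood_power=0.0
        )
        # uniform(0, 100) prior: mean 50, sd 100/sqrt(12)
        for j in range(4):
            draws = chain.samples[:, j]
            ess = float(np.asarray(az.ess(az.convert_to_dataset(draws[None, :])).x).ravel()[0])
            se = (100 / np.sqrt(12)) / np.sqrt(max(ess, 4))
            assert abs(draws.mean() - 50.0) < 3 * se


class TestSteppingStone:
    def test_degenerate_schedule_rejected(self, yule100):
        with pytest.raises(ValueError, match="stones"):
            stepping_stone_ml(yule100, np.zeros(100), np.ones(100), "independent", n_stones=1)

    def test_conjugate_toy_evidence(self):
        # y_i ~ N(theta, 1), theta ~ N(0, 1): evidence is a closed-form MVN
        y = np.random.default_rng(5).normal(1.0, 1.0, 20)
        n = len(y)

        def loglik_fn(th):
            return float(-0.5 * n * np.log(2 * np.pi) - 0.5 * np.sum((y - th[0]) ** 2))

        def log_prior_fn(th):
            return float(-0.5 * np.log(2 * np.pi) - 0.5 * th[0] ** 2)

        def sample_prior_fn(rng, nn):
            return rng.standard_normal((nn, 1))

        exact = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=np.eye(n) + 1.0)
        res = stepping_stone_evidence(
            loglik_fn, log_prior_fn, sample_prior_fn, dim=1,
            seed=3, n_stones=10, iters_per_stone=2000,
        )
        assert abs(res.log_ml - exact) < 0.2

    def test_estimator_stability_across_seeds(self, yule100):
        Q = build_rate_matrix(
            "constrained", dict(shared=1.0, q13=1.0, q31=1.5, q24=17.0, q42=2.7)
        )
        A, B = simulate_paired_ctmc(yule100, Q, 1, seed=61)
        vals = [
            stepping_stone_ml(
                yule100, A, B, "independent", n_stones=10, iters_per_stone=2000, seed=s
            ).log_ml
            for s in range(4)
        ]
        assert np.std(vals, ddof=1) < 1.0


class TestBayesFactor:
    def _fake(self, log_ml, h="x"):
        return SteppingStoneResult(
            log_ml=log_ml, betas=np.array([0.0, 1.0]), stone_mean_loglik=np.zeros(1),
            stone_contrib=np.zeros(1), n_stones=10, iters_per_stone=100, seed=0,
            model_class="m", data_hash=h,
        )

    def test_equal_evidence_is_weak(self):
        rep = log_bayes_factor(self._fake(-10.0), self._fake(-10.0))
        assert rep.log_bf == 0.0 and rep.band == "weak"

    def test_doubling_convention_and_band(self):
        rep = log_bayes_factor(self._fake(-10.0), self._fake(-35.0))
        assert rep.log_bf == pytest.approx(50.0)
        assert rep.raw_log_bf == pytest.approx(25.0)
        assert rep.band == "very strong"

    @pytest.mark.parametrize(
        "value,band",
        [(1.9, "weak"), (2.0, "positive"), (4.9, "positive"), (5.0, "strong"),
         (10.0, "strong"), (10.1, "very strong"), (-3.0, "weak")],
    )
    def test_band_boundaries(self, value, band):
        assert bf_band(value) == band

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            log_bayes_factor(self._fake(-1.0, "a"), self._fake(-2.0, "b"))


class TestTransitionSummary:
    def test_constant_chain_summary(self):
        names = ("shared", "q13", "q31", "q24", "q42")
        vals = np.array([0.5, 1.0, 1.5, 17.0, 2.7])
        chain = PagelChain(
            model_class="constrained", param_names=names,
            samples=np.tile(vals, (50, 1)), logliks=np.zeros(50),
            acceptance_rate=0.3, seed=0, data_hash="x",
        )
        summary = transition_summary(chain)
        assert summary.table.loc["q24", "mean"] == pytest.approx(17.0)
        # constrained expansion: all four B rates equal the shared value
        for qn in ("q12", "q21", "q34", "q43"):
            assert summary.table.loc[qn, "mean"] == pytest.approx(0.5)
        assert summary.ratios["q24/q42"] == pytest.approx(17.0 / 2.7)
        assert summary.ratios["q24/q31"] == pytest.approx(17.0 / 1.5)
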