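"""Synthetic-data generators: Yule trees, exact CTMC simulation, Brownian
motion, logistic responses, and the dendrobatid-like fixture."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chisquare

from phylocare import build_rate_matrix, ml_fit, parse_newick, vcv
from phylocare.simulate import (
    FIXTURE_TARGETS,
    make_dendrobatid_like_fixture,
    simulate_brownian,
    simulate_discrete,
    simulate_logistic_response,
    simulate_paired_ctmc,
    simulate_yule_tree,
)
from phylocare.trees import PhyloTree


def _star(n, length=1.0):
    parent = np.array([n] * n + [-1])
    lengths = np.array([length] * n + [0.0])
    return PhyloTree(parent, lengths, [f"t{i}" for i in range(n)])


class TestYule:
    def test_two_tip_cherry(self):
        t = simulate_yule_tree(2, seed=0)
        assert t.n_tips == 2
        assert t.is_ultrametric(tol=1e-9)

    def test_seed_determinism(self):
        assert simulate_yule_tree(20, seed=5).newick() == simulate_yule_tree(20, seed=5).newick()

    def test_height_rescaling(self):
        t = simulate_yule_tree(50, seed=1, height=1.0)
        assert t.height() == pytest.approx(1.0)
        assert t.is_ultrametric(tol=1e-9)

    def test_exponential_lineage_growth(self):
        # E[#lineages at time t] = exp(birth_rate * t) for a pure-birth process
        birth = 1.0
        counts = []
        grid = np.linspace(0.3, 2.0, 8)
        n_rep = 400
        for rep in range(n_rep):
            t = simulate_yule_tree(64, birth_rate=birth, seed=3000 + rep)
            node_depths = t.depths()[t.n_tips:]
            counts.append([1 + np.sum(node_depths < g) for g in grid])
        mean_lineages = np.asarray(counts, dtype=float).mean(axis=0)
        slope = np.polyfit(grid, np.log(mean_lineages), 1)[0]
        assert abs(slope - birth) < 0.1


class TestCtmcSimulation:
    def test_zero_rates_inherit_root(self, yule100):
        A, B = simulate_paired_ctmc(yule100, build_rate_matrix("dependent", np.zeros(8)), 4, seed=1)
        assert np.all(A == 1) and np.all(B == 1)

    def test_stationarity_on_long_branches(self):
        # independent chain, all rates equal: stationary distribution uniform
        star = _star(2000, length=5.0)
        Q = build_rate_matrix("independent", [1.0] * 4)
        A, B = simulate_paired_ctmc(star, Q, 1, seed=2)
        states = (2 * A + B).astype(int)
        freqs = np.bincount(states, minlength=4) / 2000
        se = np.sqrt(0.25 * 0.75 / 2000)
        assert np.all(np.abs(freqs - 0.25) < 3 * se + 1e-9)

    def test_matches_expm_distribution_on_two_tip_tree(self):
        # empirical tip-pair pattern frequencies vs the matrix-exponential law
        tree = parse_newick("(A:0.6,B:1.1);")
        rng_rates = dict(q12=0.4, q13=1.2, q21=0.8, q24=2.0, q31=0.3, q34=1.5, q42=0.7, q43=0.9)
        rm = build_rate_matrix("dependent", rng_rates)
        P1 = expm(rm.Q * 0.6)
        P2 = expm(rm.Q * 1.1)
        root = 0  # state 1
        expected = np.outer(P1[root], P2[root])  # joint law of (tipA_state, tipB_state)
        counts = np.zeros((4, 4))
        n_rep = 8000
        for rep in range(n_rep):
            A, B = simulate_paired_ctmc(tree, rm, 1, seed=10_000 + rep)
            s = (2 * A + B).astype(int)
            counts[s[0], s[1]] += 1
        exp_counts = expected.ravel() * n_rep
        obs = counts.ravel()
        big = exp_counts >= 5  # pool sparse cells so the chi-square is valid
        f_obs, f_exp = obs[big], exp_counts[big]
        if (~big).any():
            f_obs = np.append(f_obs, obs[~big].sum())
            f_exp = np.append(f_exp, exp_counts[~big].sum())
        stat, p = chisquare(f_obs, f_exp)
        assert p > 0.001

    def test_seed_determinism(self, yule100):
        Q = build_rate_matrix("independent", [1, 1, 1, 1])
        a1 = simulate_discrete(yule100, Q.Q, 0, seed=9)
        a2 = simulate_discrete(yule100, Q.Q, 0, seed=9)
        assert np.array_equal(a1, a2)


class TestBrownian:
    def test_vanishing_variance_pins_root(self, yule100):
        x = simulate_brownian(yule100, 1e-12, 5.0, seed=1)
        assert np.allclose(x, 5.0, atol=1e-4)

    def test_sample_covariance_matches_vcv(self, tree3):
        C = vcv(tree3).matrix
        draws = np.stack([simulate_brownian(tree3, 2.0, 0.0, seed=s) for s in range(5000)])
        emp = np.cov(draws.T)
        # MC standard error of a covariance entry is ~ sqrt(16/5000) ~ 0.057
        assert np.all(np.abs(emp - 2.0 * C) < 0.17 + 0.05 * np.abs(2.0 * C))

    def test_seed_determinism(self, yule100):
        assert np.array_equal(
            simulate_brownian(yule100, 1.0, 0.0, seed=4),
            simulate_brownian(yule100, 1.0, 0.0, seed=4),
        )


class TestLogisticResponse:
    def test_symmetric_null_rate(self):
        star = _star(2000)
        X = np.ones((2000, 1))
        y = simulate_logistic_response(star, X, np.array([0.0]), 0.0, seed=3)
        assert abs(y.mean() - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_monotone_log_odds_in_predictor(self):
        star = _star(4000)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        y = simulate_logistic_response(star, x[:, None], np.array([2.0]), 0.0, seed=6)
        bins = np.quantile(x, [0, 0.25, 0.5, 0.75, 1.0])
        rates = [
            y[(x >= bins[i]) & (x <= bins[i + 1])].mean() for i in range(4)
        ]
        assert all(rates[i] < rates[i + 1] for i in range(3))

    def test_phylogenetic_effect_raises_sister_concordance(self, yule200):
        X = np.ones((200, 1))
        y = simulate_logistic_response(yule200, X, np.array([0.0]), 8.0, seed=7)
        # cherries: pairs of tips whose parent has exactly two tip children
        cherries = []
        for node in range(yule200.n_tips, yule200.n_nodes):
            kids = yule200.children[node]
            if len(kids) == 2 and all(k < yule200.n_tips for k in kids):
                cherries.append(kids)
        sister = np.mean([y[a] == y[b] for a, b in cherries])
        rng = np.random.default_rng(8)
        perm = rng.permutation(200)
        random_pairs = np.mean(y[perm[:100]] == y[perm[100:]])
        assert sister > random_pairs


class TestFixture:
    def test_counts_within_targets(self, dendro_fixture):
        table, tree, truth = dendro_fixture
        counts = truth["counts"]
        assert tree.n_tips == FIXTURE_TARGETS["n_species"]
        for key, target in (
            ("conspicuous", FIXTURE_TARGETS["conspicuous"]),
            ("phytotelm", FIXTURE_TARGETS["phytotelm"]),
            ("caregiver_male", FIXTURE_TARGETS["caregiver_male"]),
            ("transporter_female", FIXTURE_TARGETS["transporter_female"]),
            ("habitat_near", FIXTURE_TARGETS["habitat_near"]),
        ):
            assert abs(counts[key] - target) <= 0.15 * target

    def test_byte_identical_given_seed(self, dendro_fixture):
        table, _, _ = dendro_fixture
        again, _, _ = make_dendrobatid_like_fixture(seed=1)
        assert table.to_csv(index=False) == again.to_csv(index=False)

    def test_table_matches_coding_schema(self, dendro_fixture):
        from phylocare.traits import code_trait_table

        table, tree, _ = dendro_fixture
        res = code_trait_table(table.set_index("species"), tree=tree)
        coded = res.coded
        # realistic sparsity: most continuous fields unknown for many species
        assert coded["log_clutch_size"].isna().mean() > 0.3
        assert coded["conspicuous"].notna().all()
        # segment indicators reproduce the stored score
        assert (coded["coloration_score"] >= 0).all()


class TestForwardFitLoop:
    def test_ml_error_shrinks_with_tree_size(self):
        Q = build_rate_matrix(
            "constrained", dict(shared=0.8, q13=0.5, q31=1.0, q24=6.0, q42=0.6)
        )
        errs = {}
        for n in (100, 1000):
            rel = []
            for rep in range(4):
                tree = simulate_yule_tree(n, seed=700 + rep, height=1.0)
                A, B = simulate_paired_ctmc(tree, Q, 1, seed=800 + rep)
                fit = ml_fit(tree, A, B, "constrained", n_starts=2, seed=rep)
                rel.append(abs(fit.rates["q24"] - 6.0) / 6.0)
            errs[n] = float(np.median(rel))
        assert errs[1000] < errs[100]
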