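import math

import numpy as np
import pytest

from gerrophylo import discrete as D
from gerrophylo import simulate as S
from gerrophylo.tree import Tree

from oracles import (
    enum_mk_likelihood,
    exhaustive_parsimony,
    fitch_changes,
    random_tree,
    two_state_p_matrix,
)


def _trait(tree, states):
    return D.DiscreteTrait.from_ints(
        {lab: states[lab] for lab in tree.tip_labels}, max(states.values()) + 1
    )


class TestBuildQ:
    def test_er(self):
        Q = D.build_q("ER", 3, [0.5])
        assert np.allclose(Q.sum(axis=1), 0)
        assert Q[0, 1] == Q[2, 0] == 0.5

    def test_sym_symmetric(self):
        Q = D.build_q("SYM", 3, [0.1, 0.2, 0.3])
        assert np.allclose(Q, Q.T)

    def test_ard(self):
        Q = D.build_q("ARD", 2, [0.3, 0.7])
        assert Q[0, 1] == 0.3 and Q[1, 0] == 0.7

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            D.build_q("SYM", 3, [0.1])


class TestMkLoglik:
    def test_rate_zero_closed_form(self, cherry):
        """q=0, both tips state 0, equal prior: lnL = -ln 2."""
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0}, 2)
        Q = np.zeros((2, 2))
        assert D.mk_loglik(cherry, trait, Q) == pytest.approx(-math.log(2), abs=1e-10)

    def test_cherry_closed_form(self, cherry):
        """q=1, t=0.5 per branch: L = (P00^2 + P10^2)/2."""
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0}, 2)
        Q = D.build_q("ER", 2, [1.0])
        P = two_state_p_matrix(1.0, 0.5)
        expected = math.log(0.5 * (P[0, 0] ** 2 + P[1, 0] ** 2))
        assert D.mk_loglik(cherry, trait, Q) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-1.25937, abs=1e-4)

    def test_enumeration_oracle_small(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 4))
            tree = random_tree(rng, int(rng.integers(3, 7)))
            states = {lab: int(rng.integers(k)) for lab in tree.tip_labels}
            Q = D.build_q("ARD", k, rng.uniform(0.1, 1.5, size=k * (k - 1)))
            prior = np.full(k, 1.0 / k)
            lik, _ = enum_mk_likelihood(tree, states, Q, prior)
            got = D.mk_loglik(tree, D.DiscreteTrait.from_ints(states, k), Q)
            assert got == pytest.approx(math.log(lik), abs=1e-8)

    def test_missing_tip_all_ones(self, cherry):
        trait = D.DiscreteTrait(["0", "1"], {"a": "0", "b": None})
        Q = D.build_q("ER", 2, [1.0])
        # marginalising tip b == likelihood of the a-only pattern
        got = D.mk_loglik(cherry, trait, Q)
        assert got == pytest.approx(math.log(0.5), abs=1e-10)

    def test_zero_length_branches_ok(self):
        t = Tree([-1, 0, 0], [0.0, 0.0, 0.0], [None, "a", "b"])
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0}, 2)
        got = D.mk_loglik(t, trait, D.build_q("ER", 2, [1.0]))
        assert got == pytest.approx(-math.log(2), abs=1e-10)


class TestFitMk:
    def test_constant_data_boundary(self, balanced4):
        trait = D.DiscreteTrait.from_ints({t: 0 for t in balanced4.tip_labels}, 2)
        with pytest.warns(UserWarning):
            fit = D.fit_mk(balanced4, trait, "ER")
        assert fit.lnL == pytest.approx(-math.log(2), abs=1e-6)
        assert fit.rates[0] <= 1e-7

    def test_er_equals_sym_at_k2(self):
        tree = S.simulate_tree(20, seed=3)
        tips, _ = S.simulate_discrete_trait(tree, D.build_q("ER", 2, [0.8]), 0, seed=1)
        trait = D.DiscreteTrait.from_ints(tips, 2)
        f_er = D.fit_mk(tree, trait, "ER", seed=0)
        f_sym = D.fit_mk(tree, trait, "SYM", seed=0)
        assert f_er.lnL == pytest.approx(f_sym.lnL, abs=1e-6)
        assert f_er.k_free == f_sym.k_free == 1

    def test_aicc_formula(self):
        fit = D.MkFit("ER", np.zeros((2, 2)), -10.0, 1, 0.0)
        n = 20
        expect = -2 * -10.0 + 2 * 1 + 2 * 1 * 2 / (n - 1 - 1)
        assert D._aicc(-10.0, 1, n) == pytest.approx(expect)

    def test_rate_recovery_rough(self):
        tree = S.simulate_tree(150, seed=5)
        q_true = 0.5
        tips, _ = S.simulate_discrete_trait(
            tree, D.build_q("ER", 2, [q_true]), 0, seed=7
        )
        fit = D.fit_mk(tree, D.DiscreteTrait.from_ints(tips, 2), "ER", seed=0)
        assert 0.1 < fit.rates[0] < 2.0


class TestCompareLrt:
    def _fit(self, model, lnL, k_free):
        return D.MkFit(model, np.zeros((3, 3)), lnL, k_free, 0.0)

    def test_equal_lnl_chooses_simple(self):
        p, chosen = D.compare_models_lrt(self._fit("ER", -5, 1), self._fit("SYM", -5, 3))
        assert p == 1.0 and chosen == "ER"

    def test_chi2_95th_percentile(self):
        """2 dlnL = 3.84, df 1 -> p ~ 0.050."""
        p, _ = D.compare_models_lrt(self._fit("ER", -6.92, 1), self._fit("X", -5.0, 2))
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_df_zero(self):
        p, chosen = D.compare_models_lrt(self._fit("ER", -6, 1), self._fit("SYM", -5, 1))
        assert p == 1.0 and chosen == "ER"

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            D.compare_models_lrt(self._fit("ARD", -5, 6), self._fit("ER", -5, 1))


class TestMarginals:
    def test_zero_length_children_pin_node(self):
        t = Tree(
            [-1, 0, 1, 1, 0],
            [0.0, 0.7, 0.0, 0.0, 1.0],
            [None, None, "a", "b", "c"],
        )
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0, "c": 1}, 2)
        marg = D.marginal_ancestrals(t, trait, D.build_q("ER", 2, [1.0]))
        assert marg[1][0] == pytest.approx(1.0, abs=1e-12)

    def test_cherry_root_closed_form(self, cherry):
        """P(root=0 | both tips 0) = P00^2 / (P00^2 + P10^2) ~ 0.8240."""
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0}, 2)
        marg = D.marginal_ancestrals(cherry, trait, D.build_q("ER", 2, [1.0]))
        P = two_state_p_matrix(1.0, 0.5)
        expect = P[0, 0] ** 2 / (P[0, 0] ** 2 + P[1, 0] ** 2)
        assert marg[cherry.root][0] == pytest.approx(expect, abs=1e-10)
        assert expect == pytest.approx(0.8240, abs=5e-5)

    def test_enumeration_oracle(self, rng):
        for _ in range(15):
            k = int(rng.integers(2, 4))
            tree = random_tree(rng, int(rng.integers(3, 7)))
            states = {lab: int(rng.integers(k)) for lab in tree.tip_labels}
            Q = D.build_q("SYM", k, rng.uniform(0.2, 1.0, size=k * (k - 1) // 2))
            prior = np.full(k, 1.0 / k)
            _, marg_oracle = enum_mk_likelihood(tree, states, Q, prior)
            got = D.marginal_ancestrals(tree, D.DiscreteTrait.from_ints(states, k), Q)
            for v in range(tree.n_nodes):
                assert np.allclose(got[v], marg_oracle[v], atol=1e-8)

    def test_vectors_sum_to_one(self, rng):
        tree = random_tree(rng, 8)
        states = {lab: int(rng.integers(3)) for lab in tree.tip_labels}
        got = D.marginal_ancestrals(
            tree, D.DiscreteTrait.from_ints(states, 3), D.build_q("ER", 3, [0.4])
        )
        for vec in got.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)


class TestStochasticMap:
    def test_tiny_rates_constant_history(self, balanced4):
        trait = D.DiscreteTrait.from_ints({t: 0 for t in balanced4.tip_labels}, 2)
        Q = D.build_q("ER", 2, [1e-8])
        maps = D.stochastic_map(balanced4, trait, Q, nsim=50, seed=1)
        for m in maps.maps:
            assert m.n_changes() == 0
            assert set(m.node_states().values()) == {0}

    def test_duration_conservation(self):
        tree = S.simulate_tree(10, seed=2)
        tips, _ = S.simulate_discrete_trait(tree, D.build_q("ER", 2, [1.0]), 0, seed=3)
        trait = D.DiscreteTrait.from_ints(tips, 2)
        maps = D.stochastic_map(tree, trait, D.build_q("ER", 2, [1.0]), nsim=100, seed=4)
        for m in maps.maps:
            m.validate(atol=1e-12)
            for v, segs in m.segments.items():
                for (s0, _), (s1, _) in zip(segs, segs[1:]):
                    assert s0 != s1

    def test_tip_states_respected(self):
        tree = S.simulate_tree(8, seed=6)
        tips, _ = S.simulate_discrete_trait(tree, D.build_q("ER", 2, [0.7]), 0, seed=7)
        trait = D.DiscreteTrait.from_ints(tips, 2)
        maps = D.stochastic_map(tree, trait, D.build_q("ER", 2, [0.7]), nsim=30, seed=8)
        for m in maps.maps:
            assert m.tip_states() == tips

    def test_node_frequencies_approach_marginals(self):
        tree = S.simulate_tree(8, seed=9)
        Q = D.build_q("ER", 2, [0.8])
        tips, _ = S.simulate_discrete_trait(tree, Q, 0, seed=10)
        trait = D.DiscreteTrait.from_ints(tips, 2)
        maps = D.stochastic_map(tree, trait, Q, nsim=1500, seed=11)
        marg = D.marginal_ancestrals(tree, trait, Q)
        freq = maps.node_state_frequencies()
        for v in range(tree.n_nodes):
            assert np.max(np.abs(freq[v] - marg[v])) < 0.05

    def test_seed_reproducible(self, balanced4):
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 1, "c": 0, "d": 1}, 2)
        Q = D.build_q("ER", 2, [1.0])
        m1 = D.stochastic_map(balanced4, trait, Q, nsim=20, seed=5)
        m2 = D.stochastic_map(balanced4, trait, Q, nsim=20, seed=5)
        for a, b in zip(m1.maps, m2.maps):
            assert a.segments == b.segments


class TestSankoff:
    def test_constant_tips_zero_cost(self, balanced4):
        trait = D.DiscreteTrait.from_ints({t: 0 for t in balanced4.tip_labels}, 2)
        rec = D.sankoff_parsimony(balanced4, trait)
        assert rec.total_cost == 0.0
        assert all(s == {0} for s in rec.node_states.values())

    def test_sister_pairs_one_change(self, balanced4):
        """Tips (a,b)=(0,0), (c,d)=(1,1): one change under unit costs."""
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0, "c": 1, "d": 1}, 2)
        rec = D.sankoff_parsimony(balanced4, trait, "all_equal")
        assert rec.total_cost == 1.0

    def test_exponential_prefers_intermediate(self, cherry):
        """0 -> 2 direct costs 3; two unit steps via 1 cost 2."""
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 2}, 3)
        rec = D.sankoff_parsimony(cherry, trait, "exponential")
        assert rec.total_cost == 2.0
        assert rec.node_states[cherry.root] == {1}

    def test_exhaustive_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 4))
            tree = random_tree(rng, int(rng.integers(3, 7)))
            states = {lab: int(rng.integers(k)) for lab in tree.tip_labels}
            for scheme in ("all_equal", "exponential"):
                C = D.parsimony_cost_matrix(scheme, k)
                expect = exhaustive_parsimony(tree, states, C)
                rec = D.sankoff_parsimony(
                    tree, D.DiscreteTrait.from_ints(states, k), scheme
                )
                assert rec.total_cost == pytest.approx(expect)

    def test_all_equal_matches_fitch_binary(self, rng):
        for _ in range(15):
            tree = random_tree(rng, int(rng.integers(4, 9)))
            states = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
            rec = D.sankoff_parsimony(
                tree, D.DiscreteTrait.from_ints(states, 2), "all_equal"
            )
            assert rec.total_cost == fitch_changes(tree, states)

    def test_missing_tips_allowed(self, balanced4):
        trait = D.DiscreteTrait(["0", "1"], {"a": "0", "b": None, "c": "1", "d": "1"})
        rec = D.sankoff_parsimony(balanced4, trait)
        assert rec.total_cost == 1.0

    def test_parsimony_lower_bounds_map_changes(self):
        tree = S.simulate_tree(12, seed=13)
        Q = D.build_q("ER", 2, [0.6])
        tips, _ = S.simulate_discrete_trait(tree, Q, 0, seed=14)
        trait = D.DiscreteTrait.from_ints(tips, 2)
        rec = D.sankoff_parsimony(tree, trait, "all_equal")
        maps = D.stochastic_map(tree, trait, Q, nsim=50, seed=15)
        for m in maps.maps:
            assert rec.total_cost <= m.n_changes() + 1e-9


class TestCountTransitions:
    def test_single_change_history(self, cherry):
        from gerrophylo.history import CharacterHistory

        tips = cherry.tip_indices
        hist = CharacterHistory(
            tree=cherry,
            root_state=0,
            segments={tips[0]: [(0, 0.2), (1, 0.3)], tips[1]: [(0, 0.5)]},
        )
        ts = D.count_transitions(hist, 1, state_space=["0", "1"])
        assert ts.n_origins == 1 and ts.n_reversals == 0
        assert ts.origin_branches == [tips[0]]

    def test_matches_sim_truth(self):
        tree = S.simulate_tree(20, seed=16)
        q = D.build_q("ER", 2, [0.4])
        _, truth = S.simulate_discrete_trait(tree, q, 0, seed=17)
        hist = truth.histories["trait"]
        ts = D.count_transitions(hist, 1, state_space=["0", "1"])
        assert ts.n_origins == truth.true_transition_count[("trait", 1)]

    def test_unknown_state_rejected(self):
        tree = S.simulate_tree(5, seed=1)
        tips, _ = S.simulate_discrete_trait(tree, D.build_q("ER", 2, [0.5]), 0, seed=2)
        trait = D.DiscreteTrait.from_ints(tips, 2)
        maps = D.stochastic_map(tree, trait, D.build_q("ER", 2, [0.5]), nsim=5, seed=3)
        with pytest.raises(ValueError):
            D.count_transitions(maps, "zebra")

    def test_map_set_distribution(self, balanced4):
        trait = D.DiscreteTrait.from_ints({"a": 0, "b": 0, "c": 1, "d": 1}, 2)
        Q = D.build_q("ER", 2, [0.2])
        maps = D.stochastic_map(balanced4, trait, Q, nsim=200, seed=4)
        ts = D.count_transitions(maps, "1")
        assert len(ts.origin_distribution) == 200
        # tips show the derived state: any map whose root is ancestral must gain it
        for m, n_or in zip(maps.maps, ts.origin_distribution):
            if m.root_state != 1:
                assert n_or >= 1


class TestNestingInvariant:
    def test_lnl_monotone_er_sym_ard(self):
        tree = S.simulate_tree(25, seed=19)
        q = D.build_q("SYM", 3, [0.6, 0.3, 0.4])
        tips, _ = S.simulate_discrete_trait(tree, q, 0, seed=20)
        trait = D.DiscreteTrait.from_ints(tips, 3)
        _, fits, _ = D.select_model_lrt(tree, trait, seed=0)
        assert fits["ER"].lnL <= fits["SYM"].lnL + 1e-6
        assert fits["SYM"].lnL <= fits["ARD"].lnL + 1e-6
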