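import numpy as np
import pandas as pd
import pytest

from genecontent.ancestral_counts import (
    jackknife,
    origin_nodes,
    reconstruct_all,
    reconstruct_family,
    tally_changes,
)
from genecontent.errors import ValidationError
from genecontent.synthetic_data import SimulationConfig, simulate_counts, simulate_tree
from genecontent.treeio import CountMatrix, parse_tree

from conftest import brute_force_wagner_cost, random_small_instance


class TestReconstructFamily:
    def test_constant_character_costs_nothing(self, quartet):
        states, cost = reconstruct_family(quartet, {t: 3 for t in quartet.tips})
        assert cost == 0
        assert all(s == 3 for s in states.values())

    def test_quartet_tie_breaks_to_minimum_root(self, quartet):
        states, cost = reconstruct_family(quartet, {"A": 0, "B": 0, "C": 2, "D": 2})
        assert cost == 2
        assert states["ab"] == 0 and states["cd"] == 2
        assert states["r"] == 0  # optimal interval is [0,2]; smallest wins

    def test_three_tip_example(self, cherry3):
        states, cost = reconstruct_family(cherry3, {"A": 1, "B": 1, "C": 5})
        assert cost == 4
        assert states["1"] == 1  # ancestor of the (A,B) cherry
        assert states["0"] == 1  # root

    def test_missing_tip_is_error(self, cherry3):
        with pytest.raises(ValidationError):
            reconstruct_family(cherry3, {"A": 1, "B": 1})

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            tree, tip_counts = random_small_instance(rng)
            _, cost = reconstruct_family(tree, tip_counts)
            assert cost == brute_force_wagner_cost(tree, tip_counts)

    def test_states_within_subtree_tip_range(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            tree, tip_counts = random_small_instance(rng)
            states, _ = reconstruct_family(tree, tip_counts)
            for v in tree.internal_nodes:
                sub_tips = [t for t in tree.tips
                            if v in (tree.ancestors(t) + [t])]
                lo = min(tip_counts[t] for t in sub_tips)
                hi = max(tip_counts[t] for t in sub_tips)
                assert lo <= states[v] <= hi

    def test_cost_equals_sum_of_branch_changes(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            tree, tip_counts = random_small_instance(rng)
            states, cost = reconstruct_family(tree, tip_counts)
            assert cost == sum(
                abs(states[c] - states[p]) for p, c in tree.branches()
            )

    def test_asymmetric_costs_match_generalized_oracle(self):
        import itertools

        def oracle(tree, tip_counts, a, b):
            smax = max(tip_counts.values())
            best = None
            for assign in itertools.product(range(smax + 1),
                                            repeat=len(tree.internal_nodes)):
                states = dict(zip(tree.internal_nodes, assign))
                states.update(tip_counts)
                cost = sum(
                    a * max(states[c] - states[p], 0) + b * max(states[p] - states[c], 0)
                    for p, c in tree.branches()
                )
                best = cost if best is None else min(best, cost)
            return best

        rng = np.random.default_rng(55)
        for _ in range(40):
            tree, tip_counts = random_small_instance(rng, max_tips=5)
            a, b = rng.choice([0.5, 1.0, 2.0, 3.0], size=2)
            _, cost = reconstruct_family(tree, tip_counts, gain_cost=a, loss_cost=b)
            assert cost == pytest.approx(oracle(tree, tip_counts, a, b))

    def test_expensive_losses_push_states_down(self, cherry3):
        # tips 0,0,2: with losses costly the root prefers 0 (later gains)
        _, cost_sym = reconstruct_family(cherry3, {"A": 0, "B": 0, "C": 2})
        states, cost = reconstruct_family(
            cherry3, {"A": 0, "B": 0, "C": 2}, gain_cost=1.0, loss_cost=5.0)
        assert states["0"] == 0 and cost == 2
        assert cost_sym == 2

    def test_duplicating_a_tip_never_increases_cost(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            tree, tip_counts = random_small_instance(rng, max_tips=5)
            _, cost = reconstruct_family(tree, tip_counts)
            # graft a sibling with an equal count next to the first tip
            tip = tree.tips[0]
            new_internal, new_tip = "__anc__", "__twin__"
            parent = tree.parent[tip]
            children = dict(tree.children)
            children[parent] = tuple(
                new_internal if c == tip else c for c in children[parent]
            )
            children[new_internal] = (tip, new_tip)
            children[new_tip] = ()
            par = dict(tree.parent)
            d = dict(tree.duration_my)
            half = d[tip] / 2
            par[new_internal] = parent
            par[tip] = new_internal
            par[new_tip] = new_internal
            d[new_internal] = half
            d[tip] = half
            d[new_tip] = half
            bigger = type(tree)(root=tree.root, parent=par, children=children,
                                duration_my=d)
            counts2 = dict(tip_counts)
            counts2[new_tip] = tip_counts[tip]
            _, cost2 = reconstruct_family(bigger, counts2)
            assert cost2 <= cost


class TestReconstructAll:
    def test_constant_families_zero_cost(self, quartet):
        m = CountMatrix(pd.DataFrame(
            {t: [1, 2, 0] for t in quartet.tips},
            index=["f1", "f2", "f3"],
        ))
        table = reconstruct_all(quartet, m)
        assert (table.cost == 0).all()
        assert (table.counts["r"] == [1, 2, 0]).all()

    def test_taxa_mismatch(self, quartet):
        m = CountMatrix(pd.DataFrame({"A": [1], "B": [1], "X": [1], "D": [1]},
                                     index=["f1"]))
        with pytest.raises(ValidationError):
            reconstruct_all(quartet, m)

    def test_zero_event_rate_reproduces_root_everywhere(self):
        tree = simulate_tree(6, 100.0, seed=11)
        cfg = SimulationConfig(n_families=20, gain_rate=0, loss_rate=0, seed=11)
        matrix, truth = simulate_counts(tree, cfg)
        table = reconstruct_all(tree, matrix)
        assert table.counts.loc[truth.true_counts.index, truth.true_counts.columns] \
            .equals(truth.true_counts)

    def test_costs_match_oracle_on_random_families(self):
        tree = simulate_tree(5, 50.0, seed=3)
        rng = np.random.default_rng(3)
        fams = {f"f{i}": {t: int(rng.integers(0, 5)) for t in tree.tips}
                for i in range(100)}
        m = CountMatrix(pd.DataFrame(fams).T[tree.tips])
        table = reconstruct_all(tree, m)
        for fam, counts in fams.items():
            assert table.cost[fam] == brute_force_wagner_cost(tree, counts)


class TestTally:
    def test_constant_family_contributes_nothing(self, quartet):
        m = CountMatrix(pd.DataFrame({t: [2] for t in quartet.tips}, index=["f"]))
        tally = tally_changes(reconstruct_all(quartet, m), quartet)
        assert tally.total_changes == 0
        assert tally.families_extinct == 0
        assert tally.families_emerged == 0

    def test_extinction_is_also_a_contraction(self, quartet):
        # family present in A,B only: cd side loses it entirely
        m = CountMatrix(pd.DataFrame(
            {"A": [2], "B": [2], "C": [0], "D": [0]}, index=["f"]))
        table = reconstruct_all(quartet, m)
        tally = tally_changes(table, quartet)
        rows = tally.branches.set_index("child")
        assert (rows["n_extinctions"] <= rows["n_contractions"]).all()
        assert (rows["n_emergences"] <= rows["n_expansions"]).all()
        assert tally.families_extinct + tally.families_emerged >= 1

    def test_parsimony_changes_bounded_by_true_changes(self):
        tree = simulate_tree(6, 400.0, seed=21)
        cfg = SimulationConfig(n_families=150, gain_rate=1e-3, loss_rate=1e-3, seed=21)
        matrix, truth = simulate_counts(tree, cfg)
        table = reconstruct_all(tree, matrix)
        true_cost = truth.events["delta"].abs().groupby(truth.events["family"]).sum()
        for fam in matrix.families:
            assert table.cost[fam] <= true_cost.get(fam, 0)

    def test_aggregates_sum_over_branches(self):
        tree = simulate_tree(8, 300.0, seed=4)
        cfg = SimulationConfig(n_families=80, seed=4)
        matrix, _ = simulate_counts(tree, cfg)
        tally = tally_changes(reconstruct_all(tree, matrix), tree)
        assert tally.total_changes == tally.total_expansions + tally.total_contractions
        assert tally.total_expansions == tally.branches["n_expansions"].sum()


class TestOriginNodes:
    def test_root_presence_means_ancestral(self, quartet):
        m = CountMatrix(pd.DataFrame({t: [1] for t in quartet.tips}, index=["f"]))
        table = reconstruct_all(quartet, m)
        assert origin_nodes(table, quartet)["f"] == ()

    def test_cherry_restricted_family_originates_at_cherry(self, quartet):
        m = CountMatrix(pd.DataFrame(
            {"A": [1], "B": [1], "C": [0], "D": [0]}, index=["f"]))
        table = reconstruct_all(quartet, m)
        assert origin_nodes(table, quartet)["f"] == ("ab",)


class TestJackknife:
    def _matrix(self, tree, seed=0, n=40):
        cfg = SimulationConfig(n_families=n, seed=seed)
        matrix, _ = simulate_counts(tree, cfg)
        return matrix

    def test_zero_removal_equals_full_reconstruction(self):
        tree = simulate_tree(6, 100.0, seed=1)
        matrix = self._matrix(tree, seed=1)
        table = reconstruct_all(tree, matrix)
        report = jackknife(tree, matrix, n_reps=3, n_remove=0, seed=5)
        full = table.counts.sum(axis=0)
        for v in tree.internal_nodes:
            assert report.loc[v, "sd"] == 0
            assert report.loc[v, "mean"] == full[v]

    def test_same_seed_is_deterministic(self):
        tree = simulate_tree(7, 100.0, seed=2)
        matrix = self._matrix(tree, seed=2)
        r1 = jackknife(tree, matrix, n_reps=5, n_remove=2, seed=9)
        r2 = jackknife(tree, matrix, n_reps=5, n_remove=2, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_constant_matrix_has_zero_sd(self):
        tree = simulate_tree(7, 100.0, seed=3)
        m = CountMatrix(pd.DataFrame({t: [3, 1] for t in tree.tips},
                                     index=["f1", "f2"]))
        report = jackknife(tree, m, n_reps=6, n_remove=2, seed=0)
        surviving = report[report["n_replicates"] > 0]
        assert (surviving["sd"] == 0).all()

    def test_remove_too_many_is_error(self):
        tree = simulate_tree(4, 100.0, seed=0)
        m = self._matrix(tree, seed=0, n=5)
        with pytest.raises(ValidationError):
            jackknife(tree, m, n_reps=2, n_remove=4, seed=0)
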