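import math

import numpy as np
import pytest

from mimicevo.fpk import FPKModel
from mimicevo.phylo import Node, Phylogeny, parse_tree
from mimicevo.simulate import (
    SimulationConfig,
    perturb_tree_sample,
    simulate_trait,
    simulate_tree,
    synthesize_measurements,
)
from mimicevo.traits import TRAIT_NAMES, score_traits


def _single_branch_tree(length: float) -> Phylogeny:
    # two-tip tree; tip "A" carries the branch of interest
    return parse_tree(f"(A:{length},B:{length}):0;")


class TestSimulateTree:
    def test_reproducible_and_ultrametric(self):
        t1 = simulate_tree(50, 1.0, 0.2, seed=99)
        t2 = simulate_tree(50, 1.0, 0.2, seed=99)
        assert t1.n_tips == 50
        assert t1.is_ultrametric(1e-9)
        assert t1.to_newick() == t2.to_newick()

    def test_different_seeds_differ(self):
        assert simulate_tree(20, 1.0, 0.0, seed=1).to_newick() != simulate_tree(
            20, 1.0, 0.0, seed=2
        ).to_newick()

    def test_branch_lengths_positive(self):
        for seed in range(5):
            t = simulate_tree(25, 1.0, 0.4, seed=seed)
            assert all(n.length > 0 for n in t.nodes if n.parent is not None)

    def test_infeasible_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(10, 1.0, 1.5, seed=0)
        with pytest.raises(ValueError):
            simulate_tree(10, 0.0, 0.0, seed=0)

    def test_pure_birth_height_matches_yule_expectation(self):
        # E[height] = (1/b) * sum_{k=2}^{n} 1/k for this stopping rule
        n, b, reps = 10, 1.0, 1000
        rng = np.random.default_rng(123)
        heights = np.array([simulate_tree(n, b, 0.0, seed=rng).height for _ in range(reps)])
        expected = sum(1.0 / k for k in range(2, n + 1)) / b
        se = heights.std(ddof=1) / math.sqrt(reps)
        assert abs(heights.mean() - expected) < 3 * se

    def test_pure_birth_lineages_at_half_height_match_chain_oracle(self):
        """LTT count read from the built trees vs an independent pure-birth
        chain simulation with the same stopping rule (no tree structure)."""
        n, b, reps = 10, 1.0, 2000
        rng = np.random.default_rng(123456)

        def tree_count() -> int:
            # number of branches crossing half height
            t = simulate_tree(n, b, 0.0, seed=rng)
            d = t.depths()
            tau = t.height / 2.0
            return sum(
                1
                for node in t.nodes
                if node.parent is not None and d[node.parent.id] < tau <= d[node.id]
            )

        def chain_count(rng) -> int:
            t, k = 0.0, 2
            times = []
            while k < n:
                t += rng.exponential(1.0 / (k * b))
                times.append(t)
                k += 1
            T = t + rng.exponential(1.0 / (n * b))
            return 2 + sum(1 for s in times if s <= T / 2.0)

        tree_counts = np.array([tree_count() for _ in range(reps)], dtype=float)
        chain_counts = np.array([chain_count(rng) for _ in range(reps)], dtype=float)
        se = math.sqrt(
            tree_counts.var(ddof=1) / reps + chain_counts.var(ddof=1) / reps
        )
        assert abs(tree_counts.mean() - chain_counts.mean()) < 3 * se

    def test_extinction_shortens_terminal_branches(self):
        n, reps = 10, 200
        rng = np.random.default_rng(17)

        def median_pendant(death: float) -> float:
            vals = []
            for _ in range(reps):
                t = simulate_tree(n, 1.0, death, seed=rng)
                vals.extend(tip.length for tip in t.tips)
            return float(np.median(vals))

        assert median_pendant(0.6) < median_pendant(0.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, birth_rate=1.0, death_rate=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_tips=2)


class TestSimulateTrait:
    def test_zero_height_tree_all_tips_at_root(self):
        t = parse_tree("(A:0,B:0,C:0):0;")
        for model, params in [
            ("BM", {"sigma2": 1.0, "z0": 0.7}),
            ("OU", {"sigma2": 1.0, "z0": 0.7, "alpha": 2.0}),
            ("EB", {"sigma2": 1.0, "z0": 0.7, "a": -0.5}),
        ]:
            tips, states = simulate_trait(t, model, params, seed=0)
            assert all(v == pytest.approx(0.7) for v in tips.values())
            assert states[t.root.id] == 0.7

    def test_bm_variance_law_single_branch(self):
        T, s2, reps = 2.0, 0.5, 2000
        t = _single_branch_tree(T)
        rng = np.random.default_rng(42)
        vals = np.array(
            [simulate_trait(t, "BM", {"sigma2": s2, "z0": 0.0}, seed=rng)[0]["A"] for _ in range(reps)]
        )
        assert abs(vals.var(ddof=1) / (s2 * T) - 1.0) < 0.05

    def test_ou_stationary_variance(self):
        # alpha * T >> 1: tip variance ~ sigma2/(2 alpha)
        T, s2, alpha, reps = 50.0, 2.0, 1.0, 2000
        t = _single_branch_tree(T)
        rng = np.random.default_rng(43)
        vals = np.array(
            [
                simulate_trait(t, "OU", {"sigma2": s2, "z0": 0.3, "alpha": alpha}, seed=rng)[0]["A"]
                for _ in range(reps)
            ]
        )
        assert abs(vals.var(ddof=1) / (s2 / (2 * alpha)) - 1.0) < 0.05

    def test_eb_zero_equals_bm_distribution(self):
        t = simulate_tree(10, 1.0, 0.0, seed=3)
        tips_eb, _ = simulate_trait(t, "EB", {"sigma2": 1.0, "z0": 0.0, "a": 0.0}, seed=5)
        tips_bm, _ = simulate_trait(t, "BM", {"sigma2": 1.0, "z0": 0.0}, seed=5)
        assert tips_eb == tips_bm  # identical draws given identical variance

    def test_node_states_returned_for_all_nodes(self, medium_tree):
        _, states = simulate_trait(medium_tree, "BM", {"sigma2": 1.0, "z0": 0.0}, seed=6)
        assert set(states) == {n.id for n in medium_tree.nodes}

    def test_fpk_tips_within_bounds(self, medium_tree):
        m = FPKModel(a=0.0, b=3.0, c=0.0, sigma2=1.0, bounds=(0.0, 1.0))
        tips, _ = simulate_trait(medium_tree, "FPK", {"model": m}, seed=7)
        assert all(0.0 <= v <= 1.0 for v in tips.values())

    def test_reproducibility(self, medium_tree):
        a = simulate_trait(medium_tree, "OU", {"sigma2": 1, "z0": 0, "alpha": 0.5}, seed=9)
        b = simulate_trait(medium_tree, "OU", {"sigma2": 1, "z0": 0, "alpha": 0.5}, seed=9)
        assert a == b


class TestSynthesizeMeasurements:
    def test_thin_legs_inversion(self):
        targets = {n: 0.0 for n in TRAIT_NAMES}
        targets["thin_legs"] = 0.71
        m = synthesize_measurements(targets)
        assert m.femur3_width / m.femur3_length == pytest.approx(0.29)
        assert score_traits(m).thin_legs == pytest.approx(0.71, abs=1e-12)

    def test_illusion_two_flags(self):
        targets = {n: 0.0 for n in TRAIT_NAMES}
        targets["illusion_coloration"] = 0.667
        m = synthesize_measurements(targets)
        assert sum(m.illusion_flags) == 2

    def test_all_zero_targets(self):
        targets = {n: 0.0 for n in TRAIT_NAMES}
        m = synthesize_measurements(targets)
        s = score_traits(m)
        assert np.allclose(s.as_array(), 0.0)
        assert m.illusion_flags == (False, False, False)

    def test_unreachable_illusion(self):
        targets = {n: 0.0 for n in TRAIT_NAMES}
        targets["illusion_coloration"] = 0.5
        with pytest.raises(ValueError, match="unreachable"):
            synthesize_measurements(targets)

    def test_out_of_range_rejected(self):
        targets = {n: 0.0 for n in TRAIT_NAMES}
        targets["elong_abd"] = 1.2
        with pytest.raises(ValueError):
            synthesize_measurements(targets)


class TestPerturbTreeSample:
    def test_zero_jitter_identity(self, medium_tree):
        ts = perturb_tree_sample(medium_tree, 5, 0.0, seed=1)
        assert all(w.to_newick() == medium_tree.to_newick() for w in ts)

    def test_topology_preserved(self, medium_tree):
        def bipartitions(t):
            out = set()
            below = {}
            for n in t.nodes:
                if n.is_tip:
                    below[n.id] = frozenset([n.label])
                else:
                    below[n.id] = frozenset().union(*(below[c.id] for c in n.children))
                    out.add(below[n.id])
            return out

        ts = perturb_tree_sample(medium_tree, 10, 0.1, seed=2)
        ref = bipartitions(medium_tree)
        assert all(bipartitions(w) == ref for w in ts)

    def test_trees_ultrametric_positive(self, medium_tree):
        ts = perturb_tree_sample(medium_tree, 20, 0.08, seed=3)
        for w in ts:
            assert w.is_ultrametric(1e-9)
            assert all(n.length > 0 for n in w.nodes if n.parent is not None)

    def test_mean_height_unbiased(self, medium_tree):
        ts = perturb_tree_sample(medium_tree, 200, 0.05, seed=4)
        heights = np.array([w.height for w in ts])
        assert abs(heights.mean() / medium_tree.height - 1.0) < 0.02
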