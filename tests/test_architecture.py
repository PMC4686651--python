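"""Subclone enumeration, tree compatibility, tree inference and hierarchy."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonearch import (
    CompartmentProfile,
    SimulationConfig,
    TreeCompatibilityError,
    assign_clone_fractions,
    assign_origin_compartment,
    build_genotype_matrix,
    check_tree_compatibility,
    enumerate_subclones,
    identify_founder,
    infer_clone_tree,
    mab_from_counts,
    mab_hierarchy,
    simulate_clone_tree,
    simulate_colonies,
)
from conftest import matrix_from_signatures


def brute_force_compatible(binary: pd.DataFrame):
    """Independent scan of every column pair for the three forbidden gametes."""
    cols = list(binary.columns)
    for a, b in itertools.combinations(cols, 2):
        pats = set(zip(binary[a], binary[b]))
        if {(1, 0), (0, 1), (1, 1)} <= pats:
            return False, (a, b)
    return True, None


class TestEnumerateSubclones:
    def test_counts_distinct_signatures(self, signature_matrix):
        m = signature_matrix([{"S"}, {"S"}, {"S", "J"}, {"S", "D"}], ["S", "J", "D"])
        cat = enumerate_subclones(m)
        assert cat.n_subclones == 3
        counts = {tuple(sorted(sig)): n for sig, n in cat.entries}
        assert counts == {("S",): 2, ("J", "S"): 1, ("D", "S"): 1}

    def test_all_wildtype_no_subclones(self, signature_matrix):
        m = signature_matrix([set(), set(), set()], ["S"])
        cat = enumerate_subclones(m)
        assert cat.n_subclones == 0 and cat.wildtype_count == 3

    def test_six_clone_tree_fully_sampled(self):
        cfg = SimulationConfig(n_mutations=6, branching_prob=0.5,
                               seq_error_rate=0.0, seed=61)
        tree = simulate_clone_tree(cfg)
        clone_ids = sorted(c for c in tree.clones if c != "WT")
        prof = CompartmentProfile("CD34+", {c: 1 / 7 for c in clone_ids})
        for seed in range(30):
            cfg2 = SimulationConfig(n_mutations=6, seq_error_rate=0.0, seed=seed)
            reads, truth = simulate_colonies(prof, tree, 80, cfg2)
            if set(truth.founder_clone) >= set(clone_ids):
                cat = enumerate_subclones(build_genotype_matrix(reads))
                assert cat.n_subclones == 6
                return
        pytest.fail("no seed sampled all six clones")  # pragma: no cover

    def test_nocall_colony_excluded_by_default(self, signature_matrix):
        rows = [
            {"colony_id": "c1", "mutation_id": "S", "alt_reads": 100, "total_reads": 200},
            {"colony_id": "c2", "mutation_id": "S", "alt_reads": 1, "total_reads": 5},
        ]
        m = build_genotype_matrix(pd.DataFrame(rows), panel=["S"])
        assert enumerate_subclones(m).n_evaluable == 1
        assert enumerate_subclones(m, "as_wildtype").n_evaluable == 2


class TestTreeCompatibility:
    def test_branching_signatures_compatible(self, signature_matrix):
        m = signature_matrix([{"S"}, {"S", "J"}, {"S", "D"}], ["S", "J", "D"])
        ok, pair = check_tree_compatibility(m)
        assert ok and pair is None

    def test_three_gamete_violation_detected(self, signature_matrix):
        m = signature_matrix([{"A"}, {"B"}, {"A", "B"}], ["A", "B"])
        ok, pair = check_tree_compatibility(m)
        assert not ok and pair == ("A", "B")

    def test_simulated_colonies_always_compatible(self):
        for seed in range(15):
            cfg = SimulationConfig(n_mutations=5, branching_prob=0.6,
                                   seq_error_rate=0.0, seed=seed)
            tree = simulate_clone_tree(cfg)
            clone_ids = sorted(c for c in tree.clones if c != "WT")
            prof = CompartmentProfile("CD34+", {c: 0.15 for c in clone_ids[:6]})
            reads, _ = simulate_colonies(prof, tree, 30, cfg)
            ok, _ = check_tree_compatibility(build_genotype_matrix(reads))
            assert ok

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n_col = int(rng.integers(2, 13))
            n_mut = int(rng.integers(2, 7))
            binary = pd.DataFrame(
                rng.integers(0, 2, size=(n_col, n_mut)),
                columns=[f"m{j}" for j in range(n_mut)],
            )
            assert check_tree_compatibility(binary) == brute_force_compatible(binary)


class TestInferCloneTree:
    def test_branching_example(self, signature_matrix):
        m = signature_matrix([{"S"}, {"S", "J"}, {"S", "D"}], ["S", "J", "D"])
        tree = infer_clone_tree(m)
        assert tree.parents["S"] == "WT"
        assert tree.parents["J+S"] == "S" and tree.parents["D+S"] == "S"

    def test_chain_example(self, signature_matrix):
        m = signature_matrix([{"S"}, {"S", "D"}, {"S", "D", "X"}], ["S", "D", "X"])
        tree = infer_clone_tree(m)
        assert tree.parents["D+S"] == "S" and tree.parents["D+S+X"] == "D+S"

    def test_multi_mutation_edge_when_intermediate_unobserved(self, signature_matrix):
        m = signature_matrix([{"S", "D"}, {"S", "D"}], ["S", "D"])
        tree = infer_clone_tree(m)
        assert tree.edge_mutations("D+S") == {"S", "D"}

    def test_incompatible_matrix_raises_with_pair(self, signature_matrix):
        m = signature_matrix([{"A"}, {"B"}, {"A", "B"}], ["A", "B"])
        with pytest.raises(TreeCompatibilityError) as exc:
            infer_clone_tree(m)
        assert exc.value.pair == ("A", "B")

    def test_node_count_matches_subclone_count(self, signature_matrix):
        sigs = [{"S"}, {"S"}, {"S", "J"}, {"S", "D"}, {"S", "D", "X"}, set()]
        m = signature_matrix(sigs, ["S", "J", "D", "X"])
        tree = infer_clone_tree(m)
        cat = enumerate_subclones(m)
        assert len(tree) - 1 == cat.n_subclones

    def test_round_trip_tree_to_colonies_to_tree(self):
        # simulated tree -> colonies at error 0 -> inferred tree reproduces
        # the generating clone set and parent relations (conditional on all
        # clones being sampled)
        for seed in range(10):
            cfg = SimulationConfig(n_mutations=5, branching_prob=0.5,
                                   seq_error_rate=0.0, seed=seed)
            tree = simulate_clone_tree(cfg)
            clone_ids = sorted(c for c in tree.clones if c != "WT")
            prof = CompartmentProfile("CD34+",
                                      {c: 0.9 / len(clone_ids) for c in clone_ids})
            reads, truth = simulate_colonies(prof, tree, 120, cfg)
            if set(truth.founder_clone) < set(tree.clones):
                continue
            inferred = infer_clone_tree(build_genotype_matrix(reads))
            assert inferred == tree
            return
        pytest.fail("no seed sampled every clone")  # pragma: no cover


class TestFounderAndExclusivity:
    def test_founder_present_in_all_mutant_colonies(self, signature_matrix):
        m = signature_matrix([{"S"}] * 3 + [{"S", "J"}, {"S", "D"}, set()],
                             ["S", "J", "D"])
        rep = identify_founder(m)
        assert rep.founder == {"S"}

    def test_no_universal_mutation_empty_founder(self, signature_matrix):
        m = signature_matrix([{"A"}, {"B"}], ["A", "B"])
        assert identify_founder(m).founder == frozenset()

    def test_mutual_exclusivity_requires_min_count(self, signature_matrix):
        sigs = [{"S", "J"}, {"S", "J"}, {"S", "D"}, {"S", "D"}, {"S"}]
        m = signature_matrix(sigs, ["S", "J", "D"])
        rep = identify_founder(m)
        assert ("D", "J") in rep.exclusive_pairs or ("J", "D") in rep.exclusive_pairs
        # singleton support never declares exclusivity
        m2 = signature_matrix([{"S", "J"}, {"S", "D"}, {"S", "D"}], ["S", "J", "D"])
        assert identify_founder(m2).exclusive_pairs == []

    def test_founder_labels_root_edge_of_inferred_tree(self, signature_matrix):
        m = signature_matrix([{"S"}, {"S", "J"}, {"S", "D"}], ["S", "J", "D"])
        rep = identify_founder(m)
        tree = infer_clone_tree(m)
        first = tree.children("WT")
        assert len(first) == 1 and tree.edge_mutations(first[0]) == rep.founder


class TestMabHierarchy:
    def _est(self, mut, mab, total=800):
        return mab_from_counts(int(round(mab * total)), total, mutation_id=mut,
                               sample_id="CD34")

    def test_separated_burdens_ordered(self):
        # 70% vs 60% at 800x: intervals separate, higher burden on top
        order = mab_hierarchy([self._est("DNMT3A", 0.70), self._est("SF3B1", 0.60)])
        assert order == [("DNMT3A", "SF3B1")]

    def test_similar_burdens_left_unordered(self):
        order = mab_hierarchy([self._est("SF3B1", 0.45), self._est("TET2", 0.46)])
        assert order == []

    def test_singleton_trivial(self):
        assert mab_hierarchy([self._est("SF3B1", 0.45)]) == []

    def test_mixed_samples_rejected(self):
        a = mab_from_counts(100, 800, mutation_id="x", sample_id="s1")
        b = mab_from_counts(100, 800, mutation_id="y", sample_id="s2")
        with pytest.raises(ValueError):
            mab_hierarchy([a, b])


class TestOriginCompartment:
    def test_hsc_origin(self):
        res = assign_origin_compartment(
            {"HSC": True, "MPP": True, "GMP": True, "MEP": True})
        assert res.origin == "HSC" and not res.progenitor_origin

    def test_progenitor_origin_flagged(self):
        res = assign_origin_compartment(
            {"HSC": False, "MLP": True, "GMP": True})
        assert res.origin == "MLP" and res.progenitor_origin

    def test_nowhere_detected(self):
        res = assign_origin_compartment({"HSC": False, "GMP": False})
        assert res.origin is None and not res.progenitor_origin
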