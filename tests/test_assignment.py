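import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protsym import (
    SymmetryGroup,
    SymmetryOperation,
    SyntheticSpec,
    build_partition,
    generate,
    greedy_assign,
    hungarian_assign,
    many_chains_assign,
    sequence_ordered_assign,
    validate_cycle_structure,
)
from protsym.assignment import flat_assign

from oracles import brute_force_assignment

COUNTEREXAMPLE = np.array([[0.0, 1.0], [0.5, 10.0]])


def test_hungarian_beats_greedy_on_counterexample():
    mu_h = hungarian_assign(COUNTEREXAMPLE)
    assert mu_h.tolist() == [1, 0]
    assert COUNTEREXAMPLE[[0, 1], mu_h].sum() == 1.5
    mu_g = greedy_assign(COUNTEREXAMPLE)
    # greedy grabs the 0 first and is forced into the 10
    assert mu_g.tolist() == [0, 1]
    assert COUNTEREXAMPLE[[0, 1], mu_g].sum() == 10.0


def test_zero_diagonal_gives_identity_for_both():
    cost = np.full((4, 4), 3.0)
    np.fill_diagonal(cost, 0.0)
    assert hungarian_assign(cost).tolist() == [0, 1, 2, 3]
    assert greedy_assign(cost).tolist() == [0, 1, 2, 3]


def test_hungarian_matches_brute_force_random_6x6():
    rng = np.random.default_rng(2)
    for _ in range(25):
        cost = rng.uniform(size=(6, 6))
        mu = hungarian_assign(cost)
        _, best = brute_force_assignment(cost)
        assert np.isclose(cost[np.arange(6), mu].sum(), best, atol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    k=st.integers(min_value=2, max_value=7),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_hungarian_optimal_and_greedy_never_better(k, seed):
    cost = np.random.default_rng(seed).uniform(size=(k, k))
    mu_h = hungarian_assign(cost)
    mu_g = greedy_assign(cost)
    _, best = brute_force_assignment(cost)
    rows = np.arange(k)
    assert np.isclose(cost[rows, mu_h].sum(), best, atol=1e-12)
    assert cost[rows, mu_g].sum() >= cost[rows, mu_h].sum() - 1e-12


def test_hungarian_lexicographic_tie_break():
    cost = np.ones((3, 3))  # every assignment optimal
    assert hungarian_assign(cost).tolist() == [0, 1, 2]


@pytest.mark.parametrize("bad", [np.ones((2, 3)), np.array([[0.0, np.inf], [1.0, 2.0]])])
def test_invalid_cost_matrices_rejected(bad):
    with pytest.raises(ValueError):
        hungarian_assign(bad)
    with pytest.raises(ValueError):
        greedy_assign(bad)


def test_sequence_ordered_maps_by_ordinal(clean_dimer):
    part = build_partition(clean_dimer)
    two = sequence_ordered_assign(clean_dimer, part, np.array([1, 0]))
    m = len(clean_dimer.peptides[0])
    assert two.global_perm[:m].tolist() == list(range(m, 2 * m))
    assert two.global_perm[m:].tolist() == list(range(m))


def test_many_chains_dimer_swaps_peptides(clean_dimer):
    part = build_partition(clean_dimer)
    op = SymmetryOperation(SymmetryGroup("C", 2), (0, 0, 1),
                           origin=tuple(clean_dimer.coords.mean(axis=0)))
    two = many_chains_assign(clean_dimer, part, op)
    assert two.peptide_perm.tolist() == [1, 0]
    assert two.peptide_cycle_notation(["A", "B"]) == "A → B"


def test_many_chains_never_mixes_peptides(noisy_trimer):
    s, _ = noisy_trimer
    part = build_partition(s)
    op = SymmetryOperation(SymmetryGroup("C", 3), (0.1, 0.2, 0.97),
                           origin=tuple(s.coords.mean(axis=0)))
    for strategy in ("hungarian", "greedy", "sequence"):
        two = many_chains_assign(s, part, op, strategy)
        pep_of = s.peptide_index_of_atom()
        target_pep = pep_of[two.global_perm]
        for i in range(s.n_peptides):
            sl = s.peptide_slices()[i]
            assert np.all(target_pep[sl] == two.peptide_perm[i])
        # never crosses residue boundaries or element identity
        atoms = s.atoms
        for a_idx, b_idx in enumerate(two.global_perm):
            assert atoms[a_idx].residue_seq == atoms[b_idx].residue_seq
            assert atoms[a_idx].element == atoms[b_idx].element


def test_scrambled_tetramer_recovers_planted_orbit():
    spec = SyntheticSpec(n_chains=4, group=SymmetryGroup("C", 4), seed=23,
                         scramble_chain_order=True)
    s, truth = generate(spec)
    part = build_partition(s)
    op = SymmetryOperation(SymmetryGroup("C", 4), truth.axis,
                           origin=tuple(s.coords.mean(axis=0)))
    two = many_chains_assign(s, part, op)
    assert tuple(two.peptide_perm.tolist()) == truth.peptide_orbit
    assert truth.peptide_orbit != (1, 2, 3, 0)  # actually scrambled


def test_strategy_cost_ordering_per_operation(noisy_trimer):
    s, _ = noisy_trimer
    part = build_partition(s)
    op = SymmetryOperation(SymmetryGroup("C", 3), (0.1, 0.2, 0.97),
                           origin=tuple(s.coords.mean(axis=0)))
    costs = {}
    for strategy in ("hungarian", "greedy", "sequence"):
        two = many_chains_assign(s, part, op, strategy)
        costs[strategy] = float(
            two.pair_costs[np.arange(s.n_peptides), two.peptide_perm].sum()
        )
    assert costs["hungarian"] <= costs["greedy"] + 1e-12
    assert costs["greedy"] <= costs["sequence"] + 1e-12


def test_pair_costs_invariant_under_within_class_reordering(clean_dimer):
    part = build_partition(clean_dimer)
    op = SymmetryOperation(SymmetryGroup("C", 2), (0.3, 0.1, 0.95),
                           origin=tuple(clean_dimer.coords.mean(axis=0)))
    b1 = many_chains_assign(clean_dimer, part, op).pair_costs
    # swap the two VAL CG atoms in chain B's file order (same class)
    atoms_b = list(clean_dimer.peptides[1].atoms)
    i1 = next(i for i, a in enumerate(atoms_b) if a.name == "CG1")
    i2 = next(i for i, a in enumerate(atoms_b) if a.name == "CG2")
    from dataclasses import replace
    a1, a2 = atoms_b[i1], atoms_b[i2]
    atoms_b[i1] = replace(a2, name="CG1")
    atoms_b[i2] = replace(a1, name="CG2")
    from protsym import Peptide, Structure
    s2 = Structure((clean_dimer.peptides[0],
                    Peptide("B", tuple(atoms_b))), "reordered")
    b2 = many_chains_assign(s2, build_partition(s2), op).pair_costs
    assert np.allclose(b1, b2, atol=1e-9)


def test_flat_assignment_respects_classes(noisy_trimer):
    s, _ = noisy_trimer
    part = build_partition(s)
    op = SymmetryOperation(SymmetryGroup("C", 3), (0.1, 0.2, 0.97),
                           origin=tuple(s.coords.mean(axis=0)))
    perm = flat_assign(s, part, op)
    cls = part.class_of_atom()
    assert np.all(cls[perm] == cls)


def test_cycle_structure_validator():
    group = SymmetryGroup("C", 3)
    ok = np.array([1, 2, 0, 3])          # one 3-cycle, one fixed point
    assert validate_cycle_structure(ok, group) == []
    bad = np.array([1, 0, 2, 3])          # a 2-cycle under C3
    assert validate_cycle_structure(bad, group) == [2]
    assert validate_cycle_structure(bad, SymmetryGroup("S", 2)) == []
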