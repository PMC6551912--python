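import numpy as np
import pytest

from protsym import (
    SymmetryGroup,
    SymmetryOperation,
    apply_operation,
    evaluate_csm,
    nearest_structure,
    optimal_axis,
)
from protsym.symmetry import rotation_matrix

from conftest import build_chain
from protsym.structures import Structure
from oracles import grid_search_axis, reference_csm, reference_objective


def _point_structure(points):
    chain = build_chain("A", [("GLY", i + 1, [("CA", "C", p)])
                              for i, p in enumerate(points)])
    return Structure((chain,))


@pytest.mark.parametrize("kind,n", [("C", 2), ("C", 3), ("C", 5), ("S", 2), ("S", 4), ("S", 1)])
def test_generator_matrix_properties(kind, n):
    group = SymmetryGroup(kind, n)
    op = SymmetryOperation(group, (0.3, -0.5, 0.81))
    t = op.matrix(1)
    assert np.allclose(t @ t.T, np.eye(3), atol=1e-12)
    expected_det = -1.0 if kind == "S" else 1.0
    assert np.isclose(np.linalg.det(t), expected_det, atol=1e-12)
    assert np.allclose(op.matrix(group.order), np.eye(3), atol=1e-10)


def test_apply_operation_closed_forms():
    c2z = SymmetryOperation(SymmetryGroup("C", 2), (0, 0, 1))
    out = apply_operation(c2z, np.array([[1.0, 0.0, 0.0]]), 1)
    assert np.allclose(out, [[-1.0, 0.0, 0.0]], atol=1e-12)

    inv = SymmetryOperation(SymmetryGroup("S", 2), (0, 0, 1))
    out = apply_operation(inv, np.array([[1.0, 2.0, 3.0]]), 1)
    assert np.allclose(out, [[-1.0, -2.0, -3.0]], atol=1e-12)

    mirror = SymmetryOperation(SymmetryGroup("S", 1), (0, 0, 1))
    out = apply_operation(mirror, np.array([[1.0, 2.0, 3.0]]), 1)
    assert np.allclose(out, [[1.0, 2.0, -3.0]], atol=1e-12)


def test_apply_operation_respects_origin():
    op = SymmetryOperation(SymmetryGroup("C", 2), (0, 0, 1), origin=(1.0, 0.0, 0.0))
    out = apply_operation(op, np.array([[2.0, 0.0, 0.0]]), 1)
    assert np.allclose(out, [[0.0, 0.0, 0.0]], atol=1e-12)


def test_power_equal_to_order_is_identity_on_coords():
    op = SymmetryOperation(SymmetryGroup("S", 4), (0.1, 0.7, 0.7))
    pts = np.random.default_rng(0).normal(size=(5, 3))
    assert np.allclose(apply_operation(op, pts, 4), pts, atol=1e-10)


def test_evaluate_csm_matches_reference_on_planar_toy():
    # 4 points roughly at the corners of a distorted square in the xy-plane
    pts = np.array([
        [1.0, 0.1, 0.0],
        [-0.05, 1.1, 0.05],
        [-1.1, 0.0, -0.02],
        [0.0, -0.95, 0.01],
    ])
    s = _point_structure(pts)
    group = SymmetryGroup("C", 4)
    perm = np.array([1, 2, 3, 0])
    axis = np.array([0.05, -0.02, 1.0])
    axis = axis / np.linalg.norm(axis)
    op = SymmetryOperation(group, tuple(axis))
    res = evaluate_csm(s, op, perm)
    assert np.isclose(res.s_value, reference_csm(pts, group, perm, axis), rtol=1e-12)
    assert np.isclose(res.s_value, 100.0 * res.m_value / res.norm_value, rtol=1e-12)


def test_exact_orbit_scores_zero(exact_tetramer):
    s, truth = exact_tetramer
    group = SymmetryGroup("C", 4)
    op = SymmetryOperation(group, truth.axis)
    # planted permutation: peptide orbit with identical within-chain order
    slices = s.peptide_slices()
    perm = np.empty(len(s), dtype=int)
    for i, j in enumerate(truth.peptide_orbit):
        perm[slices[i]] = np.arange(slices[j].start, slices[j].stop)
    res = evaluate_csm(s, op, perm)
    assert res.s_value <= 1e-10
    assert np.allclose(res.nearest, s.coords, atol=1e-9)


def test_nearest_structure_two_point_average():
    delta = 0.3
    pts = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, delta]])
    op = SymmetryOperation(SymmetryGroup("C", 2), (0, 0, 1), origin=(0, 0, 0))
    perm = np.array([1, 0])
    p = nearest_structure(pts, op, perm)
    # each P_k averages Q_k with T⁻¹Q_{π(k)}: z coordinates meet at δ/2
    assert np.allclose(p, [[1.0, 0.0, delta / 2], [-1.0, 0.0, delta / 2]], atol=1e-12)


def test_nearest_structure_is_symmetric_and_consistent(noisy_trimer):
    s, truth = noisy_trimer
    group = SymmetryGroup("C", 3)
    op = SymmetryOperation(group, truth.axis, origin=tuple(s.coords.mean(axis=0)))
    slices = s.peptide_slices()
    perm = np.empty(len(s), dtype=int)
    for i, j in enumerate(truth.peptide_orbit):
        perm[slices[i]] = np.arange(slices[j].start, slices[j].stop)
    p = nearest_structure(s, op, perm)
    # Eq of motion: T·P_k = P_{π(k)} for a valid cycle structure
    tp = apply_operation(op, p, 1)
    assert np.max(np.linalg.norm(tp - p[perm], axis=1)) <= 1e-9
    # numerator computed from the nearest structure equals the
    # permutation-form objective
    res = evaluate_csm(s, op, perm)
    direct = float(np.sum((s.coords - p) ** 2))
    assert np.isclose(direct, res.m_value, rtol=1e-9)


def test_optimal_axis_recovers_planted_axis(exact_tetramer):
    s, truth = exact_tetramer
    group = SymmetryGroup("C", 4)
    slices = s.peptide_slices()
    perm = np.empty(len(s), dtype=int)
    for i, j in enumerate(truth.peptide_orbit):
        perm[slices[i]] = np.arange(slices[j].start, slices[j].stop)
    op = optimal_axis(s, group, perm, init=(1, 0, 0))
    angle = np.arccos(min(1.0, abs(float(np.dot(op.axis, truth.axis)))))
    assert angle <= 1e-6


@pytest.mark.parametrize("trial", range(8))
def test_optimal_axis_matches_grid_search(trial):
    rng = np.random.default_rng(100 + trial)
    n_atoms = int(rng.integers(6, 13))
    pts = rng.normal(size=(n_atoms, 3)) * 2.0
    group = SymmetryGroup("C", int(rng.integers(2, 5))) if trial % 2 == 0 else \
        SymmetryGroup("S", 2 * int(rng.integers(2, 4)))
    perm = rng.permutation(n_atoms)
    s = _point_structure(pts)
    op = optimal_axis(s, group, perm)
    centered = pts - pts.mean(axis=0)
    ours = reference_objective(centered, group, perm, np.array(op.axis))
    _, oracle = grid_search_axis(pts, group, perm, step_deg=2.0)
    assert ours <= oracle + 1e-8


def test_inversion_axis_is_degenerate():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(6, 3))
    s = _point_structure(pts)
    init = np.array([0.6, 0.0, 0.8])
    op = optimal_axis(s, SymmetryGroup("S", 2), rng.permutation(6), init=init)
    assert op.degenerate
    assert np.allclose(op.axis, init / np.linalg.norm(init), atol=1e-12)


def test_csm_requires_noncoincident_atoms():
    pts = np.zeros((4, 3))
    s = _point_structure(pts)
    op = SymmetryOperation(SymmetryGroup("C", 2), (0, 0, 1))
    with pytest.raises(ValueError, match="coincide"):
        evaluate_csm(s, op, np.array([1, 0, 3, 2]))
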