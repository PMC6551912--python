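"""Iterative approximate CSM solver: alternate permutation and axis updates.

The CSM objective is minimized over a permutation π and an axis direction
jointly.  Neither subproblem convexifies the other, but each is exactly
solvable on its own: given the axis, the class-preserving assignment
problem yields the best π (Hungarian algorithm, two-level for homomers);
given π, the best axis is a closed-form eigen/secular solve.  The solver
alternates the two from an initial axis guess — the principal line through
the equivalence-class centroids, which for an exactly symmetric structure
*is* the symmetry axis — and stops when the axis stabilizes or the score
stops improving.  Because the assignment step optimizes only the
first-power term of the objective while scoring uses the full group sum,
the alternation can in principle oscillate; a best-so-far guard makes the
reported result monotone.  A handful of seeded restarts around the initial
guess protect against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .assignment import flat_assign, many_chains_assign, sequence_ordered_assign
from .equivalence import EquivalencePartition, build_partition
from .structures import Structure, centroid
from .symmetry import (
    CSMResult,
    SymmetryGroup,
    SymmetryOperation,
    canonical_axis_sign,
    evaluate_csm,
    optimal_axis,
)

__all__ = ["SolverConfig", "initial_axis", "solve", "solve_chirality"]


@dataclass(frozen=True)
class SolverConfig:
    """Knobs of the alternating minimization.

    axis_tolerance is the angle (radians, sign-insensitive) between
    successive axes below which the axis is considered stable;
    csm_tolerance the analogous absolute change in S.
    """

    max_iterations: int = 50
    axis_tolerance: float = 1e-6
    csm_tolerance: float = 1e-10
    restarts: int = 8
    seed: int = 0
    atom_strategy: str = "hungarian"
    many_chains: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.axis_tolerance <= 0 or self.csm_tolerance <= 0:
            raise ValueError("tolerances must be positive")


def initial_axis(
    structure: Structure,
    partition: EquivalencePartition,
    group: SymmetryGroup | None = None,
) -> np.ndarray:
    """Initial axis guess from a regression on the class centroids.

    A symmetry operation maps each equivalence class onto itself, so for a
    proper rotation every class centroid of an exactly symmetric structure
    lies *on* the axis: the orthogonal-distance best-fit line through them
    (top eigenvector of their covariance) recovers it, and remains a good
    guess under noise.  For a mirror (S1) the centroids instead lie *in*
    the mirror plane, so the guess is the plane normal (bottom
    eigenvector); for other improper groups the orbit averages collapse
    toward the origin and the guess carries little information — the
    solver's restarts do the work there.
    """
    if len(partition) < 2:
        raise ValueError("need at least 2 equivalence classes for the axis guess")
    coords = structure.coords
    cents = np.stack([coords[m].mean(axis=0) for m in partition.classes])
    cents = cents - cents.mean(axis=0)
    cov = cents.T @ cents
    if np.abs(cov).max() < 1e-18:
        return np.array([0.0, 0.0, 1.0])  # degenerate: coincident centroids
    _vals, vecs = np.linalg.eigh(cov)
    col = 0 if (group is not None and group.improper) else -1
    return canonical_axis_sign(vecs[:, col])


def _axis_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two unit axes, ignoring sign."""
    return float(np.arccos(min(1.0, abs(float(np.dot(a, b))))))


def _start_axes(guess: np.ndarray, config: SolverConfig) -> list[np.ndarray]:
    rng = np.random.default_rng(config.seed)
    starts = [np.asarray(guess, dtype=float)]
    cone_angles = [0.35, 0.8]  # rad; local escapes around the guess
    i = 0
    while len(starts) < config.restarts:
        if i < len(cone_angles):
            # random direction at a fixed angle from the guess
            perp = rng.normal(size=3)
            perp -= perp @ starts[0] * starts[0]
            nrm = np.linalg.norm(perp)
            if nrm < 1e-12:
                continue
            ang = cone_angles[i]
            starts.append(np.cos(ang) * starts[0] + np.sin(ang) * perp / nrm)
        else:
            v = rng.normal(size=3)
            nrm = np.linalg.norm(v)
            if nrm < 1e-12:
                continue
            starts.append(v / nrm)
        i += 1
    return starts[: config.restarts]


def _permute(structure, partition, op, config) -> np.ndarray:
    if config.many_chains:
        return many_chains_assign(structure, partition, op, config.atom_strategy).global_perm
    return flat_assign(structure, partition, op, config.atom_strategy)


def solve(
    structure: Structure,
    group: SymmetryGroup,
    config: SolverConfig = SolverConfig(),
    partition: EquivalencePartition | None = None,
) -> CSMResult:
    """Estimate S(G), the optimal axis/permutation and the nearest
    G-symmetric structure for a prepared multi-chain homomer."""
    if structure.n_peptides < 2:
        raise ValueError(
            "structure has a single peptide; internal (within-chain) symmetry "
            "is outside this solver's scope"
        )
    if partition is None:
        partition = build_partition(structure)
    origin = tuple(centroid(structure))
    guess = initial_axis(structure, partition, group)

    best: CSMResult | None = None
    total_iters = 0
    for start in _start_axes(guess, config):
        axis = np.asarray(start, dtype=float)
        local_best: CSMResult | None = None
        prev_s = np.inf
        converged = False
        for it in range(1, config.max_iterations + 1):
            op = SymmetryOperation(group, tuple(axis), origin)
            perm = _permute(structure, partition, op, config)
            res = evaluate_csm(structure, op, perm, compute_nearest=False)
            new_op = optimal_axis(structure, group, perm, init=axis)
            res_new = evaluate_csm(structure, new_op, perm, compute_nearest=False)
            step_best = res_new if res_new.s_value <= res.s_value else res
            if local_best is None or step_best.s_value < local_best.s_value:
                local_best = step_best
            angle = _axis_angle(axis, np.asarray(new_op.axis))
            s_now = step_best.s_value
            if angle < config.axis_tolerance or abs(prev_s - s_now) < config.csm_tolerance:
                converged = True
                total_iters += it
                break
            if s_now > prev_s + config.csm_tolerance:
                # oscillation guard: objective went up, keep best-so-far
                converged = True
                total_iters += it
                break
            axis = np.asarray(new_op.axis, dtype=float)
            prev_s = s_now
        else:
            total_iters += config.max_iterations
        local_best = dc_replace(local_best, converged=converged)
        if best is None or local_best.s_value < best.s_value:
            best = local_best
        if best.s_value <= config.csm_tolerance:
            break  # perfect symmetry found; further restarts cannot improve

    # final full evaluation (with nearest structure) at the best operation
    final = evaluate_csm(structure, best.operation, best.permutation, compute_nearest=True)
    return dc_replace(final, iterations=total_iters, converged=best.converged)


def solve_chirality(structure: Structure, config: SolverConfig = SolverConfig()) -> CSMResult:
    """Continuous chirality measure: the smaller of S(S1) (mirror) and
    S(S2) (inversion); zero iff the structure is achiral."""
    partition = build_partition(structure)
    results = [
        solve(structure, SymmetryGroup("S", 1), config, partition),
        solve(structure, SymmetryGroup("S", 2), config, partition),
    ]
    return min(results, key=lambda r: r.s_value)
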