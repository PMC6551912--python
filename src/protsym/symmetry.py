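"""Cyclic symmetry operations and the continuous symmetry measure (CSM).

The CSM of a structure Q = {Q_k} with respect to a cyclic point group G of
order n generated by an operation T is

    S(G) = 100 * M(G) / N(G)

where M(G) = min Σ_k |Q_k − P_k|² over all T-invariant structures {P_k},
and N(G) = Σ_k |Q_k − Q_0|² normalizes by the spread about the centroid
Q_0.  A candidate symmetric structure is encoded by T together with an atom
permutation π; the minimizing {P_k} is the orbit average

    P_k = (1/n) Σ_{i=1..n} T^{-i} Q_{π^i(k)}

and the objective can be rewritten purely in terms of (T, π) as

    M(G) = (1/2n) Σ_{i=1..n} Σ_k |T^i Q_k − Q_{π^i(k)}|².

This module evaluates those quantities for a fixed permutation and solves
the axis subproblem (optimal direction of T given π) in closed form: the
objective is a quadratic-plus-linear form in the unit axis vector, whose
constrained maximizer is obtained from an eigen-decomposition and a 1-D
secular equation (a trust-region-style subproblem).

Group conventions: Cn is a proper rotation by 360°/n.  Sn is rotation by
360°/n composed with reflection through the plane perpendicular to the
axis; for odd n the generated cyclic group has order 2n (S1 = mirror, S2 =
inversion, both of effective order 2), and all group sums run over the true
group order so that T^order = identity always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import Structure, centroid

__all__ = [
    "SymmetryGroup",
    "SymmetryOperation",
    "CSMResult",
    "rotation_matrix",
    "apply_operation",
    "evaluate_csm",
    "nearest_structure",
    "optimal_axis",
    "canonical_axis_sign",
]

_AXIS_TOL = 1e-12
_IDENTITY_TOL = 1e-10


@dataclass(frozen=True)
class SymmetryGroup:
    """Cyclic point group: proper Cn ('C') or improper Sn ('S')."""

    kind: str  # "C" or "S"
    n: int

    def __post_init__(self) -> None:
        if self.kind not in ("C", "S"):
            raise ValueError(f"group kind must be 'C' or 'S', got {self.kind!r}")
        if self.n < 1 or (self.kind == "C" and self.n < 2):
            raise ValueError(f"invalid group order n={self.n} for kind {self.kind}")

    @property
    def improper(self) -> bool:
        return self.kind == "S"

    @property
    def order(self) -> int:
        """Number of elements of the generated cyclic group.

        For odd-n improper groups the generator squares to a pure rotation,
        so the cyclic group has 2n elements (S1 -> 2, mirror plus identity).
        """
        if self.improper and self.n % 2 == 1:
            return 2 * self.n
        return self.n

    @classmethod
    def from_string(cls, text: str) -> "SymmetryGroup":
        text = text.strip().upper()
        if len(text) < 2 or text[0] not in "CS" or not text[1:].isdigit():
            raise ValueError(f"cannot parse symmetry group {text!r} (expected e.g. 'C4', 'S2')")
        return cls(text[0], int(text[1:]))

    def __str__(self) -> str:
        return f"{self.kind}{self.n}"


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < _AXIS_TOL:
        raise ValueError("axis vector has zero norm")
    return v / norm


def rotation_matrix(axis: Sequence[float], angle: float, improper: bool = False) -> np.ndarray:
    """Rotation by *angle* about *axis*; composed with the reflection
    through the plane perpendicular to the axis when *improper*."""
    v = _unit(axis)
    c, s = np.cos(angle), np.sin(angle)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    mat = c * np.eye(3) + s * vx + (1 - c) * np.outer(v, v)
    if improper:
        mat = (np.eye(3) - 2 * np.outer(v, v)) @ mat
    return mat


@dataclass(frozen=True)
class SymmetryOperation:
    """The generator T of a cyclic group: group, unit axis, and origin."""

    group: SymmetryGroup
    axis: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            object.__setattr__(self, "axis", tuple(_unit(v)))

    def matrix(self, power: int = 1) -> np.ndarray:
        """Matrix of T^power (about the origin-translated frame)."""
        angle = 2.0 * np.pi * power / self.group.n
        improper = self.group.improper and (power % 2 == 1)
        return rotation_matrix(self.axis, angle, improper)

    def matrices(self) -> list[np.ndarray]:
        """[T^1, ..., T^order]; the last is the identity."""
        return [self.matrix(i) for i in range(1, self.group.order + 1)]


def apply_operation(op: SymmetryOperation, coords: np.ndarray, power: int = 1) -> np.ndarray:
    """Apply T^power about the operation's axis through its origin."""
    coords = np.asarray(coords, dtype=float)
    origin = np.asarray(op.origin, dtype=float)
    return (coords - origin) @ op.matrix(power).T + origin


def _permutation_powers(permutation: np.ndarray, order: int) -> list[np.ndarray]:
    """[π^1, ..., π^order] as index arrays."""
    permutation = np.asarray(permutation, dtype=int)
    powers = []
    cur = permutation
    for _ in range(order):
        powers.append(cur)
        cur = permutation[cur]
    return powers


@dataclass(frozen=True)
class CSMResult:
    """Outcome of one CSM evaluation or solve."""

    s_value: float
    m_value: float
    norm_value: float
    operation: SymmetryOperation
    permutation: np.ndarray
    nearest: np.ndarray
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        assert -1e-9 <= self.s_value <= 100.0 + 1e-9, self.s_value


def nearest_structure(
    structure: Structure | np.ndarray,
    op: SymmetryOperation,
    permutation: np.ndarray,
) -> np.ndarray:
    """Orbit-averaged nearest G-symmetric coordinates P_k.

    When π's cycle structure is compatible with the group (cycle lengths 1,
    2 or n), the output satisfies T·P_k = P_{π(k)} exactly.
    """
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure, float)
    origin = np.asarray(op.origin, dtype=float)
    q = coords - origin
    order = op.group.order
    acc = np.zeros_like(q)
    for i, pi_i in enumerate(_permutation_powers(permutation, order), start=1):
        acc += q[pi_i] @ op.matrix(-i).T
    return acc / order + origin


def evaluate_csm(
    structure: Structure,
    op: SymmetryOperation,
    permutation: np.ndarray,
    compute_nearest: bool = True,
) -> CSMResult:
    """Score a fixed (operation, permutation) pair.

    The numerator is the permutation-form objective
    (1/2n) Σ_i Σ_k |T^i Q_k − Q_{π^i(k)}|²; the denominator is the spread
    about the centroid.
    """
    coords = structure.coords
    n_atoms = coords.shape[0]
    permutation = np.asarray(permutation, dtype=int)
    if sorted(permutation.tolist()) != list(range(n_atoms)):
        raise ValueError("permutation is not a permutation of all atom indices")
    q0 = centroid(structure)
    q = coords - q0
    norm_value = float(np.sum(q * q))
    if norm_value <= 0.0:
        raise ValueError("all atoms coincide; CSM undefined (zero normalization)")

    op = SymmetryOperation(op.group, op.axis, tuple(q0), op.degenerate)
    order = op.group.order
    total = 0.0
    for i, pi_i in enumerate(_permutation_powers(permutation, order), start=1):
        diff = q @ op.matrix(i).T - q[pi_i]
        total += float(np.sum(diff * diff))
    m_value = total / (2.0 * order)
    s_value = min(100.0 * m_value / norm_value, 100.0)

    nearest = (
        nearest_structure(coords, op, permutation) if compute_nearest else np.empty((0, 3))
    )
    return CSMResult(
        s_value=s_value,
        m_value=m_value,
        norm_value=norm_value,
        operation=op,
        permutation=permutation,
        nearest=nearest,
    )


def canonical_axis_sign(axis: np.ndarray) -> np.ndarray:
    """Flip the axis so its first component of magnitude > 1e-12 is positive."""
    axis = np.asarray(axis, dtype=float)
    for comp in axis:
        if abs(comp) > _AXIS_TOL:
            return axis if comp > 0 else -axis
    return axis


def _axis_quadratic_form(
    q: np.ndarray,
    group: SymmetryGroup,
    permutation: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Reduce the fixed-π objective to  f(v) = base − 2(const + vᵀMv + wᵀv).

    Using Rodrigues' formula, (T^i a)·b for rotation by θ_i about v is
    cosθ a·b + sinθ v·(a×b) + (1−cosθ)(v·a)(v·b); for the improper odd
    powers the reflection flips the axial component, changing the last
    coefficient to (−1−cosθ).  Summing over group powers and atoms gives a
    symmetric matrix M, vector w and constant; base = 2·order·Σ|q|².
    """
    order = group.order
    m_mat = np.zeros((3, 3))
    w = np.zeros(3)
    const = 0.0
    for i, pi_i in enumerate(_permutation_powers(permutation, order), start=1):
        theta = 2.0 * np.pi * i / group.n
        c, s = np.cos(theta), np.sin(theta)
        improper_step = group.improper and (i % 2 == 1)
        kappa = (-1.0 - c) if improper_step else (1.0 - c)
        a, b = q, q[pi_i]
        const += c * float(np.sum(a * b))
        w += s * np.cross(a, b).sum(axis=0)
        outer = a.T @ b
        m_mat += kappa * 0.5 * (outer + outer.T)
    base = 2.0 * order * float(np.sum(q * q))
    return m_mat, w, const, base


def _maximize_on_sphere(m_mat: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Maximize h(v) = vᵀMv + wᵀv over the unit sphere.

    Returns (argmax, max value, degenerate flag).  Solved via the
    stationarity condition (λI − M)v = w/2 with λ ≥ λ_max(M): a secular
    equation in λ, with the usual hard case when w ⟂ the top eigenspace.
    """
    scale = max(np.abs(m_mat).max(), np.abs(w).max(), 1e-30)
    eigvals, eigvecs = np.linalg.eigh(m_mat)
    d_max = eigvals[-1]
    if scale < 1e-20 or (eigvals[-1] - eigvals[0] < 1e-12 * scale and np.linalg.norm(w) < 1e-12 * scale):
        # objective is (numerically) independent of the axis
        return np.array([0.0, 0.0, 1.0]), float(d_max), True

    wt = eigvecs.T @ (w / 2.0)
    top = eigvals > d_max - 1e-12 * scale

    def v_of(lam: float) -> np.ndarray:
        return wt / (lam - eigvals)

    if np.linalg.norm(wt[top]) <= 1e-11 * scale:
        # hard case: w has no component on the top eigenspace
        rest = ~top
        v_perp = np.zeros(3)
        v_perp[rest] = wt[rest] / (d_max - eigvals[rest])
        norm2 = float(np.dot(v_perp, v_perp))
        if norm2 <= 1.0:
            j = int(np.argmax(top))
            v_perp[j] = np.sqrt(1.0 - norm2)
            v = eigvecs @ v_perp
            val = float(v @ m_mat @ v + w @ v)
            return v, val, False
        # fall through: root exists above d_max

    # bracket the unique root of ||v(λ)|| = 1 on (d_max, ∞)
    lo = d_max + 1e-14 * scale
    while np.linalg.norm(v_of(lo)) <= 1.0:
        lo = d_max + (lo - d_max) * 0.5
        if lo - d_max < 1e-300:
            break
    hi = d_max + max(np.linalg.norm(wt), 1e-14 * scale)
    while np.linalg.norm(v_of(hi)) > 1.0:
        hi = d_max + 2.0 * (hi - d_max)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.linalg.norm(v_of(mid)) > 1.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-16 * max(abs(hi), 1.0):
            break
    v = eigvecs @ v_of(0.5 * (lo + hi))
    nv = np.linalg.norm(v)
    if nv > 0:
        v = v / nv
    val = float(v @ m_mat @ v + w @ v)
    return v, val, False


def optimal_axis(
    structure: Structure | np.ndarray,
    group: SymmetryGroup,
    permutation: np.ndarray,
    init: Sequence[float] = (0.0, 0.0, 1.0),
) -> SymmetryOperation:
    """Best symmetry axis for a fixed permutation, in closed form.

    Minimizes the permutation-form objective over unit axis vectors.  The
    origin is pinned at the structure centroid.  When the objective does not
    depend on the axis (e.g. S2 inversion, or isotropic degeneracy) the
    *init* direction is returned with ``degenerate=True``.
    """
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure, float)
    q0 = coords.mean(axis=0)
    q = coords - q0
    permutation = np.asarray(permutation, dtype=int)

    m_mat, w, _const, _base = _axis_quadratic_form(q, group, permutation)
    v, _val, degenerate = _maximize_on_sphere(m_mat, w)
    if degenerate:
        v = _unit(init)
    else:
        init_u = _unit(init)
        if float(init_u @ m_mat @ init_u + w @ init_u) > float(v @ m_mat @ v + w @ v) + 1e-12:
            v = init_u  # closed form should never lose; guard anyway
        # sign canonicalization only when it cannot change the objective
        if abs(float(w @ v)) <= 1e-10 * max(float(np.abs(m_mat).max()), 1e-30):
            v = canonical_axis_sign(v)
    return SymmetryOperation(group=group, axis=tuple(v), origin=tuple(q0), degenerate=degenerate)
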