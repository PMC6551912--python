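"""Class-preserving atom permutations for a fixed symmetry operation.

Three atom-level strategies are provided:

* ``hungarian`` — the exact solution of the assignment problem on the
  squared-distance cost matrix A_ij = |T Q_i − Q_j|² (per equivalence
  class), via the Hungarian algorithm;
* ``greedy`` — repeatedly pair the globally closest unassigned (row, col);
  fast but suboptimal;
* ``sequence`` — map atoms by their within-chain serial order, ignoring
  geometry entirely.

The *many chains* composition applies assignment at two levels: the lower
level finds, for every ordered peptide pair (i, j), the best
class-preserving atom map and its cost B_ij; the upper level runs the
Hungarian algorithm on the ℓ×ℓ matrix B to pick the peptide permutation.
The composed global permutation carries each peptide in its entirety onto
another peptide and never crosses residue boundaries.

Only the first-power term of the full CSM objective drives these costs;
the full objective is evaluated afterwards by the scoring layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .equivalence import EquivalencePartition
from .structures import Structure
from .symmetry import SymmetryOperation, apply_operation

__all__ = [
    "hungarian_assign",
    "greedy_assign",
    "sequence_ordered_assign",
    "many_chains_assign",
    "flat_assign",
    "TwoLevelPermutation",
    "validate_cycle_structure",
    "ATOM_STRATEGIES",
]

ATOM_STRATEGIES = ("hungarian", "greedy", "sequence")

_LEX_CANONICAL_MAX = 16


def _check_cost(cost: np.ndarray) -> np.ndarray:
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    return cost


def hungarian_assign(cost: np.ndarray) -> np.ndarray:
    """Globally optimal assignment μ minimizing Σ_i cost[i, μ(i)].

    For small matrices the result is canonicalized to the lexicographically
    smallest optimal assignment, making ties deterministic.
    """
    cost = _check_cost(cost)
    k = cost.shape[0]
    rows, cols = linear_sum_assignment(cost)
    mu = np.empty(k, dtype=int)
    mu[rows] = cols
    if k <= 1 or k > _LEX_CANONICAL_MAX:
        return mu
    best = float(cost[rows, cols].sum())
    tol = 1e-9 * max(1.0, abs(best))
    # fix rows in order to the smallest column that still allows optimality
    free_cols = list(range(k))
    fixed_cost = 0.0
    out = np.empty(k, dtype=int)
    for i in range(k):
        sub_rows = list(range(i + 1, k))
        for j in sorted(free_cols):
            if i == k - 1:
                rest = 0.0
            else:
                rem_cols = [c for c in free_cols if c != j]
                sub = cost[np.ix_(sub_rows, rem_cols)]
                r, c = linear_sum_assignment(sub)
                rest = float(sub[r, c].sum())
            if fixed_cost + cost[i, j] + rest <= best + tol:
                out[i] = j
                fixed_cost += cost[i, j]
                free_cols.remove(j)
                break
        else:  # numerical safety: fall back to scipy's optimum
            return mu
    return out


def greedy_assign(cost: np.ndarray) -> np.ndarray:
    """Pair the globally smallest remaining entry until all rows assigned.

    Ties break to the smallest (row, column).  Cost is never below the
    Hungarian optimum and the permutation may be strictly worse.
    """
    cost = _check_cost(cost)
    k = cost.shape[0]
    work = cost.copy()
    mu = np.full(k, -1, dtype=int)
    for _ in range(k):
        flat = int(np.argmin(work))  # row-major argmin = (row, col) tie-break
        i, j = divmod(flat, k)
        mu[i] = j
        work[i, :] = np.inf
        work[:, j] = np.inf
    return mu


@dataclass(frozen=True)
class TwoLevelPermutation:
    """Peptide-level permutation plus per-pair atom maps, composed globally."""

    peptide_perm: np.ndarray              # peptide i -> peptide_perm[i]
    atom_maps: dict                       # (i, peptide_perm[i]) -> within-chain index map
    global_perm: np.ndarray               # flat atom permutation π
    pair_costs: np.ndarray | None = None  # the ℓ×ℓ matrix B (first-power costs)

    def peptide_cycle_notation(self, chain_ids: list[str]) -> str:
        """Human-readable cycles, e.g. 'A → C → D → B → E'."""
        seen = set()
        parts = []
        for start in range(len(self.peptide_perm)):
            if start in seen:
                continue
            cyc = [start]
            seen.add(start)
            nxt = int(self.peptide_perm[start])
            while nxt != start:
                cyc.append(nxt)
                seen.add(nxt)
                nxt = int(self.peptide_perm[nxt])
            parts.append(" → ".join(chain_ids[c] for c in cyc))
        return " ; ".join(parts)


def sequence_ordered_assign(
    structure: Structure,
    partition: EquivalencePartition,
    peptide_perm: np.ndarray,
) -> TwoLevelPermutation:
    """Atoms map by their within-chain ordinal; no geometric optimization."""
    slices = structure.peptide_slices()
    lengths = {sl.stop - sl.start for sl in slices}
    if len(lengths) != 1:
        raise ValueError("peptides have mismatched lengths; prepare the structure first")
    m = lengths.pop()
    peptide_perm = np.asarray(peptide_perm, dtype=int)
    global_perm = np.empty(len(structure), dtype=int)
    atom_maps = {}
    ident = np.arange(m)
    for i, j in enumerate(peptide_perm):
        atom_maps[(i, int(j))] = ident
        global_perm[slices[i]] = np.arange(slices[int(j)].start, slices[int(j)].stop)
    return TwoLevelPermutation(peptide_perm, atom_maps, global_perm)


def _classes_by_pair_size(
    partition: EquivalencePartition,
    structure: Structure,
) -> dict[int, np.ndarray]:
    """Group classes by per-peptide multiplicity.

    Returns {size: array of shape (n_classes, ℓ, size)} of *within-chain*
    atom ordinals, atoms sorted by flat index inside each peptide cell.
    """
    slices = structure.peptide_slices()
    starts = np.array([sl.start for sl in slices])
    pep_of = structure.peptide_index_of_atom()
    n_pep = structure.n_peptides
    grouped: dict[int, list[np.ndarray]] = {}
    for members in partition.classes:
        size = len(members) // n_pep
        cell = np.empty((n_pep, size), dtype=int)
        for p in range(n_pep):
            mine = np.sort(members[pep_of[members] == p])
            cell[p] = mine - starts[p]
        grouped.setdefault(size, []).append(cell)
    return {size: np.stack(cells) for size, cells in grouped.items()}


def _pair_cost_and_maps(
    q: np.ndarray,
    tq: np.ndarray,
    slices: list[slice],
    grouped: dict[int, np.ndarray],
    i: int,
    j: int,
    strategy: str,
    m_atoms: int,
) -> tuple[float, np.ndarray]:
    """Best class-preserving cost of mapping peptide i onto peptide j under T.

    Returns (B_ij, within-chain index map ν: ordinal u of peptide i ->
    ordinal ν[u] of peptide j).
    """
    si, sj = slices[i], slices[j]
    if strategy == "sequence":
        d = tq[si] - q[sj]
        return float(np.sum(d * d)), np.arange(m_atoms)

    nu = np.empty(m_atoms, dtype=int)
    total = 0.0
    for size, cells in grouped.items():
        rows = cells[:, i, :]  # (ncls, size) ordinals in peptide i
        cols = cells[:, j, :]
        if size == 1:
            a = tq[si.start + rows[:, 0]]
            b = q[sj.start + cols[:, 0]]
            d = a - b
            total += float(np.sum(d * d))
            nu[rows[:, 0]] = cols[:, 0]
        elif size == 2:
            a = tq[si.start + rows]          # (ncls, 2, 3)
            b = q[sj.start + cols]
            # c[x, y] = |a_x - b_y|² per class
            diff = a[:, :, None, :] - b[:, None, :, :]
            c = np.sum(diff * diff, axis=-1)  # (ncls, 2, 2)
            direct = c[:, 0, 0] + c[:, 1, 1]
            crossed = c[:, 0, 1] + c[:, 1, 0]
            if strategy == "hungarian":
                use_cross = crossed < direct
                total += float(np.sum(np.where(use_cross, crossed, direct)))
            else:  # greedy: complement of the globally smallest entry
                flat = c.reshape(len(c), 4)
                amin = np.argmin(flat, axis=1)  # row-major = (row, col) tie-break
                use_cross = (amin == 1) | (amin == 2)
                total += float(np.sum(np.where(use_cross, crossed, direct)))
            nu[rows[:, 0]] = np.where(use_cross, cols[:, 1], cols[:, 0])
            nu[rows[:, 1]] = np.where(use_cross, cols[:, 0], cols[:, 1])
        else:
            # general class size (e.g. hydrogens kept): small dense solves
            assign = hungarian_assign if strategy == "hungarian" else greedy_assign
            for cls in range(cells.shape[0]):
                r, cset = rows[cls], cols[cls]
                diff = tq[si.start + r][:, None, :] - q[sj.start + cset][None, :, :]
                c = np.sum(diff * diff, axis=-1)
                mu = assign(c)
                total += float(c[np.arange(size), mu].sum())
                nu[r] = cset[mu]
    return total, nu


def many_chains_assign(
    structure: Structure,
    partition: EquivalencePartition,
    op: SymmetryOperation,
    atom_strategy: str = "hungarian",
) -> TwoLevelPermutation:
    """Two-level assignment: optimal atom maps per peptide pair, then the
    optimal peptide permutation over the pair-cost matrix B.

    The upper level is always solved exactly (Hungarian); *atom_strategy*
    controls only the lower, within-pair level.
    """
    if atom_strategy not in ATOM_STRATEGIES:
        raise ValueError(f"unknown atom strategy {atom_strategy!r}")
    n_pep = structure.n_peptides
    slices = structure.peptide_slices()
    m_atoms = slices[0].stop - slices[0].start
    q = structure.coords
    tq = apply_operation(op, q, 1)
    grouped = _classes_by_pair_size(partition, structure)

    b_mat = np.empty((n_pep, n_pep))
    maps: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n_pep):
        for j in range(n_pep):
            b_mat[i, j], maps[(i, j)] = _pair_cost_and_maps(
                q, tq, slices, grouped, i, j, atom_strategy, m_atoms
            )

    if n_pep == 1:
        peptide_perm = np.array([0])
    else:
        peptide_perm = hungarian_assign(b_mat)

    global_perm = np.empty(len(structure), dtype=int)
    atom_maps = {}
    for i, j in enumerate(peptide_perm):
        nu = maps[(i, int(j))]
        atom_maps[(i, int(j))] = nu
        global_perm[slices[i]] = slices[int(j)].start + nu
    return TwoLevelPermutation(peptide_perm, atom_maps, global_perm, pair_costs=b_mat)


def flat_assign(
    structure: Structure,
    partition: EquivalencePartition,
    op: SymmetryOperation,
    atom_strategy: str = "hungarian",
) -> np.ndarray:
    """Per-class assignment over *all* peptides at once (no peptide level).

    This is the single-level baseline: permutations may map different atoms
    of one peptide into different peptides.
    """
    if atom_strategy == "sequence":
        raise ValueError("sequence strategy requires a peptide permutation; use many_chains_assign")
    assign = hungarian_assign if atom_strategy == "hungarian" else greedy_assign
    q = structure.coords
    tq = apply_operation(op, q, 1)
    global_perm = np.empty(len(structure), dtype=int)
    for members in partition.classes:
        diff = tq[members][:, None, :] - q[members][None, :, :]
        cost = np.sum(diff * diff, axis=-1)
        mu = assign(cost)
        global_perm[members] = members[mu]
    return global_perm


def validate_cycle_structure(permutation: np.ndarray, group) -> list[int]:
    """Cycle lengths of π that are incompatible with the group.

    Valid lengths are 1, 2 (only for S-type groups or C2) and the group
    order n.  The assignment solvers deliberately do not enforce this; the
    result is diagnostic only.
    """
    permutation = np.asarray(permutation, dtype=int)
    allowed = {1, group.order}
    if group.improper or group.order == 2:
        allowed.add(2)
    bad = []
    seen = np.zeros(len(permutation), dtype=bool)
    for start in range(len(permutation)):
        if seen[start]:
            continue
        length = 0
        k = start
        while not seen[k]:
            seen[k] = True
            k = int(permutation[k])
            length += 1
        if length not in allowed:
            bad.append(length)
    return bad
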