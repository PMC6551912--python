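# Methods

## The measure

For a structure with atom coordinates Q = {Q_k : 1 ≤ k ≤ N} and a cyclic
point group G generated by an operation T (proper rotation by 360°/n for
C_n; rotation–reflection for S_n), the continuous symmetry measure is

    S(G) = 100 · M(G) / N(G),
    M(G) = min Σ_k |Q_k − P_k|²   over all T-invariant {P_k},
    N(G) = Σ_k |Q_k − Q_0|²,      Q_0 the unweighted centroid.

A T-invariant candidate is parametrized by T and an atom permutation π via
T·P_k = P_{π(k)}; the minimizing candidate for fixed (T, π) is the orbit
average P_k = (1/n) Σ_{i=1..n} T^{−i} Q_{π^i(k)}, and the objective can be
written without P as

    M(G) = (1/2n) Σ_{i=1..n} Σ_k |T^i Q_k − Q_{π^i(k)}|².

Both forms are implemented and agree to 1e-9 relative whenever π has a
cycle structure compatible with the group (cycle lengths 1, 2, or n); the
test suite asserts this identity and the exact T-invariance of the orbit
average. S is dimensionless, invariant under rigid motion and uniform
scaling of the input, and ranges 0–100 (0 = exact symmetry). Near-
symmetric protein homomers typically score below ~3: the denominator for
an extended quaternary structure is much larger than the per-atom
deviations in the numerator.

**Group conventions.** The generator of S_n with odd n does not satisfy
T^n = E (S1 is a mirror: T² = E), so for odd-n improper groups all group
sums run over the true cyclic-group order 2n. S1 and S2 are thus both
order-2 groups (mirror + identity, inversion + identity); their minimum is
reported as the continuous chirality measure (CCM). Even-n S_n and all
C_n use order n exactly. Only single-generator cyclic groups are
supported; dihedral and polyhedral groups are out of scope.

## Equivalence classes ("use sequence")

π may only exchange atoms of identical chemical identity: same element,
residue type and residue sequence number (with insertion code). On top of
this, an explicit per-residue table merges the chemically interchangeable
branch pairs — Val CG1/CG2, Leu CD1/CD2, Phe/Tyr CD1/CD2 and CE1/CE2, Arg
NH1/NH2, Asp OD1/OD2, Glu OE1/OE2 — into one class under a canonical
label. The table is deliberately not derived by stripping digits from
atom names: Ile CG1/CG2 label topologically distinct branches, and
Asn/Gln/His near-pairs differ in element or ring position, so none of
those merge. For hydrogen-free structures every class therefore holds
exactly ℓ or 2ℓ atoms (ℓ = number of peptides); hydrogens are deleted by
default during preparation, so the 3ℓ methyl-type classes do not arise in
the default pipeline.

## Assignment

For a fixed operation T the best class-preserving permutation minimizes
Σ A_{iμ(i)} with A_ij = |T Q_{a_i} − Q_{a_j}|² per class — an assignment
problem, solved exactly in O(k³) by the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`, with a lexicographic
canonicalization layer for deterministic tie-breaks on matrices up to
16×16, which covers every class- and peptide-level matrix in practice).
Only the i = 1 term of the full objective drives these costs; the full
group sum is used for scoring. Two baselines are kept for comparison:
greedy (repeatedly take the globally smallest remaining entry;
tie-break by smallest (row, column)) and sequence-ordered (map atoms by
their within-chain ordinal, geometry ignored). Per class,
cost(Hungarian) ≤ cost(greedy) ≤ cost(sequence) always.

**Many-chains composition.** To guarantee the permutation carries each
peptide wholly onto another peptide, assignment runs at two levels: for
every ordered peptide pair (i, j) the lower level finds the best
class-preserving atom map and its cost B_ij (the per-class subproblems
restricted to a pair have size 1 or 2, so this is vectorized:
singleton classes map directly, doubleton classes compare the direct vs
crossed pairing); the upper level runs the Hungarian algorithm on B to
choose the peptide permutation, and the stored pair maps are composed
into the global π. The upper level is always solved exactly; the
`atom_strategy` option switches only the lower level. A single-level
(`many_chains=False`) mode that assigns per class across all peptides at
once is kept as the historical baseline.

The cycle-structure restriction on π (cycles of length 1, 2, or n) is
*not* enforced during assignment — there is no efficient assignment
algorithm under such constraints — and the composed π can violate it
(e.g. branch-pair maps need not compose to the identity around a peptide
cycle). A post-hoc validator reports offending cycle lengths; scoring
always uses the permutation-form objective, which is defined for any π.

## Axis optimization

For fixed π the objective is quadratic in the axis: using Rodrigues'
formula, Σ_i Σ_k (T^i Q_k)·Q_{π^i(k)} = const + wᵀv + vᵀMv with M
symmetric (the reflection part of improper powers only flips the sign of
the axial coefficient). Maximizing vᵀMv + wᵀv on the unit sphere is a
trust-region-style subproblem: stationarity gives (λI − M)v = w/2 with
λ ≥ λ_max(M), solved by bisection on the secular equation ‖v(λ)‖ = 1 in
the eigenbasis of M, with the standard hard case (w orthogonal to the top
eigenspace) handled explicitly. When the objective is numerically
independent of the axis (S2 inversion; isotropic degeneracy) the supplied
initial direction is returned with a degeneracy flag. The closed form is
verified against a dense 2° unit-sphere grid search plus Nelder-Mead
refinement of an independently coded term-by-term objective (agreement to
1e-8 on random problems).

The axis sign is canonicalized (first nonzero component positive) only
when flipping cannot change the objective — for a fixed π with a nonzero
linear term, v and −v score differently and the optimal sign is returned.
Consequently a recovered orbit may be the planted cycle or its inverse;
the two describe the same symmetry group, and tests and the acceptance
script accept either. The operation origin is pinned at the centroid and
never optimized: the normalization is defined about Q_0 and the orbit
average about any other point would not minimize the displacement.

## The iterative solver

`solve` alternates the two exact subproblem solvers: axis → permutation
(two-level Hungarian) → axis → … starting from the centroid-regression
guess. Each equivalence class is preserved by the symmetry operation, so
for an exactly symmetric structure every class centroid lies on the
rotation axis; the orthogonal-distance best-fit line through the class
centroids (top eigenvector of their covariance) is therefore the natural
initial guess and recovers the axis exactly at zero noise. For a mirror
(S1) the centroids lie in the mirror plane instead, so the guess is the
plane normal (bottom eigenvector); for other improper groups the orbit
averages collapse toward the origin and restarts carry the search.

Convergence is declared when the angle between successive axes
(sign-insensitive) drops below `axis_tolerance` (default 1e-6 rad) or the
change in S below `csm_tolerance` (default 1e-10); a best-so-far guard
stops a start whose objective increases, which can happen because the
assignment step optimizes the i = 1 term while scoring uses the full
group sum. Defaults: 50 max iterations (typically 2–4 are used), 8
starts — the analytic guess, two seeded directions at fixed angles
(0.35 / 0.8 rad) from it, and seeded random unit vectors. Identical
inputs and configuration produce bit-identical results.

`solve_chirality` runs S1 and S2 and returns the smaller measure.

## Preparation

Raw PDB input is reduced to scoreable form in two idempotent stages.
`clean` removes HETATM records, blocklisted solvent residues (HOH etc.),
hydrogens (by default — most deposited files lack them, and removing them
unifies inputs), and all but the first-listed occurrence of each atom
name within a residue (the "first alternate location", robust to a blank
altloc preceding a lettered one); chains containing nucleic-acid residues
are rejected outright. `harmonize_chains` then deletes, from every chain,
any residue position or atom name absent from at least one chain —
whether declared in REMARK 465/470 or detected by direct cross-chain
comparison, so header-stripped files work — and reorders atoms within
each residue to the first chain's order. The result satisfies the
prepared-structure invariant (identical (residue, atom) sequences across
peptides, asserted on every call); an irreconcilable position (different
residue names at one residue number) is an error naming the position.
Both stages return a report of everything removed.

PDB I/O is a strict fixed-width reader/writer for ATOM/TER/MODEL records:
first model only, parse errors carry line numbers, elements fall back to
name-based inference when columns 77–78 are absent, and
read∘write round-trips field-for-field (coordinates to 1e-3 Å; verified
against an independent parser in the tests).

## Synthetic fixtures

The generator builds one template chain of pseudo-residues (real residue
names and PDB-legal atom names over a GLY/VAL/ALA/LEU/SER/ASP cycle, so
preparation and class construction run unchanged), replicates it into an
exact T-orbit about a planted axis, and adds isotropic Gaussian
displacement noise of standard deviation σ per coordinate. Default
geometry: 8 residues per chain on a gentle helix of ~6 Å radius with
randomized local frames — asymmetric enough to avoid accidental extra
symmetry, with class centroids well spread along the axis. σ defaults to
0 (exact orbit); test scenarios use σ in the 0.05–0.5 Å range, bracketing
crystallographic coordinate uncertainty. Two adversarial options emulate
deposition artifacts: scrambled chain file order (the correct peptide
permutation is not the file order) and swapped branch labels (the
coordinates of each interchangeable pair are exchanged between their name
slots in alternating chains, so sequence-ordered mapping pairs the
geometrically wrong partners while the class structure is unchanged).

What the fixtures do *not* emulate: real bond lengths and angles,
secondary structure, correlated (B-factor-like) displacement, conformer
heterogeneity, or partially swapped labels within a chain. Passing tests
therefore demonstrate the correctness of the optimization machinery and
its statistical behavior under displacement noise — not preparation
fidelity on every real-world PDB dialect, which only the opt-in benchmark
against deposited structures exercises.

## Numerical choices and limitations

- Tolerances: T^order = identity and nearest-structure invariance to
  1e-10/1e-9; unit axes to 1e-12; assignment tie-breaks lexicographic.
- Degenerate inputs: all-coincident atoms (N(G) = 0) raise; coincident
  class centroids fall back to the z-axis with a degeneracy flag;
  single-peptide structures are rejected (internal symmetry of domains is
  out of scope).
- The solver is a local method with restarts, not a global optimizer: on
  pathological geometries the reported S is an upper bound on the true
  minimum. On all planted-ground-truth fixtures in the suite it attains
  the optimum.
- Problem sizes in the shipped tests and acceptance script (chains of
  6–8 pseudo-residues, 20–50 replicates per noise level, 100–1000 random
  oracle problems) were chosen to exercise every code path with
  comfortable statistical margins at interactive runtimes; all scale
  linearly if enlarged.
- Scoring clamps S at 100 for pathological permutations (the theoretical
  0–100 scale assumes a compatible π; arbitrary π can exceed it).
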