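# protsym

Continuous symmetry and chirality measures for multi-chain protein
structures.

Most protein homomers are *nearly* — but not exactly — symmetric, and the
deviation carries structural and functional information. `protsym`
quantifies that deviation: given a homomer of ℓ peptides and a cyclic
point group *G* of order *n* (proper rotations *C₂ … C₆ …* or improper
rotations *S₁* = mirror, *S₂* = inversion, *S₄ …*), it computes the
continuous symmetry measure

```
S(G) = 100 · M(G) / N(G)

M(G) = min Σₖ |Qₖ − Pₖ|²          over all G-symmetric structures {Pₖ}
N(G) = Σₖ |Qₖ − Q₀|²              (spread about the centroid Q₀)
```

together with the optimal symmetry axis, the atom permutation π realizing
the symmetry, and the nearest perfectly symmetric structure
`Pₖ = (1/n) Σᵢ T⁻ⁱ Q_{πⁱ(k)}` (writable as a PDB file). `S = 0` means
exact symmetry; near-symmetric crystal structures typically score in the
0–3 range, and the improper groups give the continuous chirality measure
(CCM).

Minimizing over π and the axis jointly is the hard part: the permutation
space is astronomically large. `protsym` uses the sequence-aware
approximate algorithm:

* atoms may only interchange within **equivalence classes** — same
  element, residue type and residue number, with the chemically
  interchangeable branch pairs (Val CG1/CG2, Leu CD1/CD2, Phe/Tyr ring
  pairs, Arg NH1/NH2, Asp OD1/OD2, Glu OE1/OE2) sharing a class;
* for a fixed axis, the optimal class-preserving permutation is found by
  the **Hungarian algorithm at two levels**: per peptide pair on the atoms
  (cost `|T·Qᵢ − Qⱼ|²`), then on the ℓ×ℓ matrix of pair costs to pick the
  peptide permutation — so each peptide is carried onto another peptide in
  its entirety;
* for a fixed permutation, the optimal axis is solved in **closed form**
  (an eigen-decomposition plus a one-dimensional secular equation);
* the two exact subproblem solvers are **alternated** from an initial axis
  guess (the principal line through the equivalence-class centroids) until
  the axis stabilizes, with seeded restarts against local minima.

The greedy and sequence-ordered (file-order) atom-assignment baselines are
included for comparison, as are the preparation pipeline for raw PDB files
(solvent/ligand/hydrogen/altloc handling, cross-chain harmonization of
missing residues and atoms) and a generator of synthetic homomers with
planted ground truth.

## Worked example

```python
from protsym import (SolverConfig, SymmetryGroup, SyntheticSpec,
                     build_partition, generate, many_chains_assign, solve)

group = SymmetryGroup("C", 4)
spec = SyntheticSpec(n_chains=4, group=group, axis=(0.25, -0.35, 0.9),
                     seed=44, scramble_chain_order=True)
structure, truth = generate(spec)           # exact C4 orbit, scrambled file order
result = solve(structure, group, SolverConfig(restarts=3))
two = many_chains_assign(structure, build_partition(structure), result.operation)
print(result.s_value)                        # 5.2e-30  -> numerically zero
print(two.peptide_cycle_notation([p.chain_id for p in structure.peptides]))
# 'A → C → D → B'  -> the recovered peptide orbit, not the file order
```

The measure is numerically zero because the input is exactly symmetric,
and the peptide cycle shows which chain the 90° rotation maps onto which —
recovered from geometry, not from the order of the chains in the file.
With Gaussian coordinate noise the measure rises smoothly
(median S(C₃) over 10 replicates, from `examples/02_noise_response.py`):

```
 sigma (A)   median S(C3)   axis error (deg)
      0.00         0.0000              0.000
      0.05         0.0103              0.057
      0.10         0.0411              0.113
      0.20         0.1642              0.228
      0.50         1.0117              0.578
```

Each script in `examples/` demonstrates one capability: exact symmetry
recovery, the noise response, the Hungarian-vs-baseline comparison, the
chirality measure, and the PDB preparation pipeline.

A thin CLI wraps the same library calls:

```
protsym calc --group c5 --out results/ structure.pdb
protsym prep raw.pdb --out prepared.pdb --report prep.json
protsym compare --group c2 --variant sequence *.pdb
```

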