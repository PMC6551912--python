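"""Why geometric atom assignment matters: Hungarian vs. alternatives.

The fixture is a near-symmetric homodimer in which the interchangeable
branch atoms (Val CG1/CG2, Leu CD1/CD2, Asp OD1/OD2) carry *swapped*
labels in the second chain — a common deposition artifact.  Mapping atoms
by their file order (the sequence-ordered baseline) then pairs each branch
atom with the geometrically wrong partner and overestimates the asymmetry;
the Hungarian assignment inside each equivalence class finds the true
pairing.
"""

from protsym import SolverConfig, SymmetryGroup, SyntheticSpec, generate, relative_error, solve

group = SymmetryGroup("C", 2)
spec = SyntheticSpec(
    n_chains=2, group=group, noise_sigma=0.25, seed=62, swap_branch_labels=True,
)
structure, _ = generate(spec)

scores = {}
for strategy in ("hungarian", "greedy", "sequence"):
    cfg = SolverConfig(restarts=2, atom_strategy=strategy)
    scores[strategy] = solve(structure, group, cfg).s_value
    print(f"S(C2) with {strategy:>9} assignment = {scores[strategy]:.4f}")

err = relative_error(scores["hungarian"], scores["sequence"])
print()
print(f"relative error of the sequence-ordered baseline: {err:.1f}%")
print("Hungarian <= greedy <= sequence-ordered always holds; here the")
print("baseline overstates the distortion because every swapped branch pair")
print("is charged the full wrong-partner distance.")
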