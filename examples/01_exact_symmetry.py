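"""Score a perfectly C4-symmetric synthetic tetramer.

Builds four identical pseudo-peptides arranged as an exact 4-fold orbit
about a planted axis (with the chains deliberately written in scrambled
file order), then runs the solver.  A measure of ~0 means the structure is
indistinguishable from its nearest C4-symmetric counterpart; the recovered
axis and peptide cycle should match what was planted.
"""

import numpy as np

from protsym import (
    SolverConfig,
    SymmetryGroup,
    SyntheticSpec,
    build_partition,
    generate,
    many_chains_assign,
    solve,
)

group = SymmetryGroup("C", 4)
spec = SyntheticSpec(
    n_chains=4,
    group=group,
    axis=(0.25, -0.35, 0.9),
    seed=44,
    scramble_chain_order=True,
)
structure, truth = generate(spec)
result = solve(structure, group, SolverConfig(restarts=3))

two_level = many_chains_assign(structure, build_partition(structure), result.operation)
chain_ids = [p.chain_id for p in structure.peptides]
angle = np.degrees(
    np.arccos(min(1.0, abs(float(np.dot(result.operation.axis, truth.axis)))))
)

print(f"S(C4)              = {result.s_value:.3e}")
print(f"axis error         = {angle:.2e} degrees from the planted axis")
print(f"peptide cycle      = {two_level.peptide_cycle_notation(chain_ids)}")
print(f"planted orbit      = {truth.peptide_orbit} (file-order indices)")
print(f"iterations         = {result.iterations}, converged = {result.converged}")
print()
print("S ~ 1e-30 is numerical zero: the structure is exactly C4-symmetric,")
print("and the cycle shows which chain maps onto which under the rotation.")
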