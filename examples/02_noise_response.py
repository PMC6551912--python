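"""How the symmetry measure responds to coordinate noise.

Generates C3 trimers whose atoms are displaced by isotropic Gaussian noise
of increasing amplitude and reports the median measure over replicates.
S grows smoothly from zero with distortion — that is the point of a
*continuous* symmetry measure, as opposed to a yes/no classification.
"""

import numpy as np

from protsym import SolverConfig, SymmetryGroup, SyntheticSpec, generate, solve

group = SymmetryGroup("C", 3)
print(f"{'sigma (A)':>10} {'median S(C3)':>14} {'axis error (deg)':>18}")
for sigma in [0.0, 0.05, 0.1, 0.2, 0.5]:
    values, angles = [], []
    for rep in range(10):
        spec = SyntheticSpec(
            n_chains=3, group=group, residues_per_chain=6,
            axis=(0.2, -0.1, 0.97), noise_sigma=sigma, seed=900 + rep,
        )
        structure, truth = generate(spec)
        res = solve(structure, group, SolverConfig(restarts=2))
        values.append(res.s_value)
        angles.append(np.degrees(np.arccos(min(1.0, abs(
            float(np.dot(res.operation.axis, truth.axis)))))))
    print(f"{sigma:>10.2f} {np.median(values):>14.4f} {np.median(angles):>18.3f}")

print()
print("The measure rises monotonically with the distortion amplitude while")
print("the recovered axis stays within a fraction of a degree of the truth.")
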