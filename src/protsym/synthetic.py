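"""Synthetic homomer fixtures with planted ground truth.

Every test in the suite that needs a multi-chain structure builds it here:
one template chain of pseudo-residues (real residue names, PDB-legal atom
names, so preparation and equivalence-class construction run unchanged) is
replicated into an exact Cn/Sn orbit about a planted axis, then perturbed
by isotropic Gaussian displacement noise of chosen amplitude.  Optional
adversarial twists mimic real deposition artifacts:

* ``scramble_chain_order`` — chains appear in the file in an order
  unrelated to the geometric orbit, so the correct peptide permutation is
  not the file order;
* ``swap_branch_labels`` — in alternating chains the coordinates of each
  interchangeable branch pair (e.g. Val CG1/CG2) are exchanged between
  their name slots, the situation where depositors' branch labels disagree
  geometrically between chains and sequence-ordered mapping pays for it.

The geometry is deliberately not physical (no bond-length realism); only
the combinatorial and statistical structure matters for these tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .equivalence import interchangeable_atoms
from .structures import Atom, Peptide, Structure, write_pdb
from .symmetry import SymmetryGroup, SymmetryOperation, rotation_matrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "write_fixture_pdb"]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

# atom offsets (Å) from the residue anchor; branch pairs get distinct,
# non-mirror-related offsets so the template has no accidental symmetry
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (-1.20, 0.45, -0.30)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.25, 0.60, 0.35)),
        ("O", "O", (1.55, 1.70, 0.80)),
    ],
    "ALA": [
        ("N", "N", (-1.20, 0.45, -0.30)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.25, 0.60, 0.35)),
        ("O", "O", (1.55, 1.70, 0.80)),
        ("CB", "C", (-0.45, -1.35, 0.65)),
    ],
    "SER": [
        ("N", "N", (-1.20, 0.45, -0.30)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.25, 0.60, 0.35)),
        ("O", "O", (1.55, 1.70, 0.80)),
        ("CB", "C", (-0.45, -1.35, 0.65)),
        ("OG", "O", (-1.55, -2.05, 0.10)),
    ],
    "VAL": [
        ("N", "N", (-1.20, 0.45, -0.30)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.25, 0.60, 0.35)),
        ("O", "O", (1.55, 1.70, 0.80)),
        ("CB", "C", (-0.45, -1.35, 0.65)),
        ("CG1", "C", (-1.75, -1.95, 0.20)),
        ("CG2", "C", (0.55, -2.40, 0.95)),
    ],
    "LEU": [
        ("N", "N", (-1.20, 0.45, -0.30)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.25, 0.60, 0.35)),
        ("O", "O", (1.55, 1.70, 0.80)),
        ("CB", "C", (-0.45, -1.35, 0.65)),
        ("CG", "C", (-0.95, -2.45, -0.25)),
        ("CD1", "C", (-2.30, -2.95, 0.20)),
        ("CD2", "C", (0.05, -3.60, -0.35)),
    ],
    "ASP": [
        ("N", "N", (-1.20, 0.45, -0.30)),
        ("CA", "C", (0.00, 0.00, 0.00)),
        ("C", "C", (1.25, 0.60, 0.35)),
        ("O", "O", (1.55, 1.70, 0.80)),
        ("CB", "C", (-0.45, -1.35, 0.65)),
        ("CG", "C", (-0.95, -2.45, -0.25)),
        ("OD1", "O", (-2.15, -2.65, -0.45)),
        ("OD2", "O", (-0.10, -3.25, -0.75)),
    ],
}

_BRANCH_CYCLE = ["GLY", "VAL", "ALA", "LEU", "SER", "ASP"]
_PLAIN_CYCLE = ["GLY", "ALA", "SER"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic homomer."""

    n_chains: int
    residues_per_chain: int = 8
    group: SymmetryGroup = SymmetryGroup("C", 2)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sigma: float = 0.0
    seed: int = 0
    include_branch_residues: bool = True
    scramble_chain_order: bool = False
    swap_branch_labels: bool = False

    def __post_init__(self) -> None:
        if self.n_chains % self.group.order != 0:
            raise ValueError(
                f"n_chains={self.n_chains} must be a multiple of the group order "
                f"{self.group.order} for a full planted orbit"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted; the solver should recover it."""

    axis: tuple[float, float, float]
    peptide_orbit: tuple[int, ...]  # file-order peptide i maps onto orbit[i] under T
    group: str
    noise_sigma: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis": list(self.axis),
                "peptide_orbit": list(self.peptide_orbit),
                "group": self.group,
                "noise_sigma": self.noise_sigma,
                "seed": self.seed,
            },
            indent=2,
        )


def _template_chain(spec: SyntheticSpec, rng: np.random.Generator):
    """One chain as (names, elements, resnames, resseqs, coords) along +z."""
    cycle = _BRANCH_CYCLE if spec.include_branch_residues else _PLAIN_CYCLE
    names, elements, resnames, resseqs, coords = [], [], [], [], []
    n_res = spec.residues_per_chain
    for r in range(n_res):
        resname = cycle[r % len(cycle)]
        radius = 6.0 + 0.6 * rng.uniform(-1, 1)
        phi = 0.42 * r + 0.12 * rng.uniform(-1, 1)
        z = 1.8 * r - 0.9 * (n_res - 1)
        anchor = np.array([radius * np.cos(phi), radius * np.sin(phi), z])
        # per-residue random orientation of the local frame
        rot = rotation_matrix(rng.normal(size=3), rng.uniform(0, 2 * np.pi))
        for name, element, offset in _RESIDUE_TEMPLATES[resname]:
            names.append(name)
            elements.append(element)
            resnames.append(resname)
            resseqs.append(r + 1)
            coords.append(anchor + rot @ np.array(offset))
    return names, elements, resnames, resseqs, np.array(coords)


def generate(spec: SyntheticSpec) -> tuple[Structure, GroundTruth]:
    """Build the homomer described by *spec* plus its ground truth.

    Deterministic for a fixed spec (all randomness flows from spec.seed).
    With noise_sigma = 0 the coordinates form an exact orbit: applying the
    planted operation maps chain c onto chain orbit(c) with zero residual.
    """
    rng = np.random.default_rng(spec.seed)
    order = spec.group.order
    n_templates = spec.n_chains // order
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    op = SymmetryOperation(spec.group, tuple(axis), (0.0, 0.0, 0.0))

    chains = []  # (names, elements, resnames, resseqs, coords)
    orbit: dict[int, int] = {}
    idx = 0
    for t in range(n_templates):
        names, elements, resnames, resseqs, base = _template_chain(spec, rng)
        if t > 0:  # displace extra templates radially so they do not overlap
            base = base + np.array([0.0, 0.0, 25.0 * t])
        first = idx
        for i in range(order):
            coords = base @ op.matrix(i).T
            chains.append((names, elements, resnames, resseqs, coords))
            orbit[idx] = first + (i + 1) % order
            idx += 1

    if spec.noise_sigma > 0:
        for _, _, _, _, coords in chains:
            coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    if spec.swap_branch_labels:
        # exchange coordinates of each interchangeable pair between its
        # name slots in every odd-index chain (labels/order untouched)
        for ci in range(1, len(chains), 2):
            names, _, resnames, resseqs, coords = chains[ci]
            by_res: dict[tuple[int, str], dict[str, int]] = {}
            for ai, (nm, rn, rs) in enumerate(zip(names, resnames, resseqs)):
                by_res.setdefault((rs, rn), {})[nm] = ai
            for (rs, rn), name_map in by_res.items():
                for pair in interchangeable_atoms(rn):
                    a, b = (name_map[p] for p in pair)
                    coords[[a, b]] = coords[[b, a]]

    file_order = list(range(spec.n_chains))
    if spec.scramble_chain_order:
        file_order = list(rng.permutation(spec.n_chains))
    # orbit re-expressed over file positions
    pos_of = {chain: pos for pos, chain in enumerate(file_order)}
    peptide_orbit = tuple(pos_of[orbit[file_order[pos]]] for pos in range(spec.n_chains))

    peptides = []
    serial = 1
    for pos, chain in enumerate(file_order):
        names, elements, resnames, resseqs, coords = chains[chain]
        cid = _CHAIN_IDS[pos]
        atoms = []
        for nm, el, rn, rs, xyz in zip(names, elements, resnames, resseqs, coords):
            atoms.append(
                Atom(
                    serial=serial,
                    name=nm,
                    element=el,
                    residue_name=rn,
                    residue_seq=rs,
                    insertion_code="",
                    chain_id=cid,
                    coords=tuple(float(x) for x in xyz),
                )
            )
            serial += 1
        peptides.append(Peptide(cid, tuple(atoms)))

    structure = Structure(tuple(peptides), source_id=f"synthetic-{spec.group}-{spec.seed}")
    truth = GroundTruth(
        axis=tuple(axis),
        peptide_orbit=peptide_orbit,
        group=str(spec.group),
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
    )
    return structure, truth


def write_fixture_pdb(structure: Structure, truth: GroundTruth, directory: str | Path) -> tuple[Path, Path]:
    """Persist the fixture as PDB + ground-truth JSON; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pdb_path = directory / f"{structure.source_id}.pdb"
    json_path = directory / f"{structure.source_id}.truth.json"
    write_pdb(structure, pdb_path)
    json_path.write_text(truth.to_json() + "\n")
    return pdb_path, json_path
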