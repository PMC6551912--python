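import numpy as np
import pytest

from protsym import (
    Atom,
    Peptide,
    Structure,
    SymmetryGroup,
    SyntheticSpec,
    generate,
)


def make_atom(serial, name, element, resname, resseq, chain, xyz, **kw):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_seq=resseq,
        insertion_code=kw.pop("icode", ""),
        chain_id=chain,
        coords=tuple(float(v) for v in xyz),
        **kw,
    )


def build_chain(chain_id, residues, start_serial=1, offset=(0.0, 0.0, 0.0)):
    """residues: list of (resname, resseq, [(atom_name, element, xyz), ...])."""
    atoms = []
    serial = start_serial
    off = np.asarray(offset, float)
    for resname, resseq, atom_specs in residues:
        for name, element, xyz in atom_specs:
            atoms.append(
                make_atom(serial, name, element, resname, resseq, chain_id,
                          np.asarray(xyz, float) + off)
            )
            serial += 1
    return Peptide(chain_id, tuple(atoms))


ALA_ATOMS = [
    ("N", "N", (-1.2, 0.4, -0.3)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, 0.6, 0.3)),
    ("O", "O", (1.5, 1.7, 0.8)),
    ("CB", "C", (-0.5, -1.3, 0.6)),
]
VAL_ATOMS = ALA_ATOMS[:4] + [
    ("CB", "C", (-0.5, -1.3, 0.6)),
    ("CG1", "C", (-1.8, -2.0, 0.2)),
    ("CG2", "C", (0.6, -2.4, 1.0)),
]
GLY_ATOMS = ALA_ATOMS[:4]


@pytest.fixture
def clean_dimer():
    """Two identical chains, already clean and harmonized."""
    residues = [("ALA", 1, ALA_ATOMS), ("VAL", 2, VAL_ATOMS), ("GLY", 3, GLY_ATOMS)]
    a = build_chain("A", residues)
    b = build_chain("B", residues, start_serial=100, offset=(12.0, 3.0, -4.0))
    return Structure((a, b), source_id="clean-dimer")


@pytest.fixture
def exact_tetramer():
    spec = SyntheticSpec(n_chains=4, group=SymmetryGroup("C", 4),
                         axis=(0.2, -0.3, 0.93), seed=42)
    return generate(spec)


@pytest.fixture
def noisy_trimer():
    spec = SyntheticSpec(n_chains=3, group=SymmetryGroup("C", 3),
                         axis=(0.1, 0.2, 0.97), noise_sigma=0.1, seed=17)
    return generate(spec)
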