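"""Sequence-aware equivalence classes constraining the atom permutation.

A symmetry permutation of a homomer may only exchange atoms of identical
chemical identity: same element, same residue type, same residue sequence
number (and insertion code).  On top of that, a handful of side chains are
locally symmetric — the two Cγ of Val, the two Cδ of Leu, the ring carbon
pairs of Phe/Tyr, the terminal N pair of Arg and O pairs of Asp/Glu — whose
branch labels are chemically interchangeable.  Atoms in such a pair share
one *canonical label* and hence one class.

For a hydrogen-free homomer of ℓ peptides every class therefore has size ℓ
(unique atom names) or 2ℓ (interchangeable pairs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structures import Structure

__all__ = [
    "EquivalenceKey",
    "EquivalencePartition",
    "interchangeable_atoms",
    "build_partition",
]

logger = logging.getLogger(__name__)

# Chemically interchangeable atom-name groups per residue type.  This is an
# explicit table, not digit-stripping: Ile's CG1/CG2 sit on branches of
# different topology and must stay distinct, and Asn/Gln/His "pairs" differ
# in element or aromatic position.
_INTERCHANGEABLE: dict[str, tuple[tuple[str, ...], ...]] = {
    "VAL": (("CG1", "CG2"),),
    "LEU": (("CD1", "CD2"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
    "ARG": (("NH1", "NH2"),),
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


def interchangeable_atoms(residue_name: str) -> list[tuple[str, ...]]:
    """Interchangeable atom-name groups for a residue type (possibly empty)."""
    return list(_INTERCHANGEABLE.get(residue_name.upper(), ()))


@dataclass(frozen=True)
class EquivalenceKey:
    """What atoms must agree on to be allowed to interchange."""

    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    canonical_label: str


@dataclass(frozen=True)
class EquivalencePartition:
    """Disjoint cover of all atom indices by interchangeability classes."""

    classes: tuple[np.ndarray, ...]
    keys: tuple[EquivalenceKey, ...]
    n_atoms: int
    n_peptides: int

    def __len__(self) -> int:
        return len(self.classes)

    def class_of_atom(self) -> np.ndarray:
        out = np.full(self.n_atoms, -1, dtype=int)
        for ci, members in enumerate(self.classes):
            out[members] = ci
        return out

    def to_json(self) -> str:
        payload = [
            {
                "key": vars(k),
                "atoms": members.tolist(),
            }
            for k, members in zip(self.keys, self.classes)
        ]
        return json.dumps(payload, indent=2)


def _canonical_label(residue_name: str, atom_name: str) -> str:
    for group in _INTERCHANGEABLE.get(residue_name.upper(), ()):
        if atom_name in group:
            return "/".join(sorted(group))
    return atom_name


def build_partition(structure: Structure) -> EquivalencePartition:
    """Partition a prepared structure's atoms into equivalence classes.

    Classes are keyed by (element, residue type, residue number + insertion
    code, canonical atom label) and listed deterministically by residue
    number, then canonical label.  Raises if the per-peptide balance that a
    prepared homomer guarantees is violated.
    """
    if not structure.is_prepared():
        raise ValueError("build_partition requires a prepared structure "
                         "(identical identity sequences across peptides)")
    atoms = structure.atoms
    n_peptides = structure.n_peptides
    pep_of = structure.peptide_index_of_atom()

    buckets: dict[EquivalenceKey, list[int]] = {}
    for idx, a in enumerate(atoms):
        res = a.residue_name.upper()
        if res not in _STANDARD_RESIDUES and res not in _INTERCHANGEABLE:
            if a.name and a.name[-1].isdigit():
                logger.warning(
                    "unknown residue %s: digit-suffixed atom %s kept distinct",
                    res, a.name,
                )
        key = EquivalenceKey(
            element=a.element,
            residue_name=res,
            residue_seq=a.residue_seq,
            insertion_code=a.insertion_code,
            canonical_label=_canonical_label(res, a.name),
        )
        buckets.setdefault(key, []).append(idx)

    order = sorted(
        buckets,
        key=lambda k: (k.residue_seq, k.insertion_code, k.canonical_label,
                       k.element, k.residue_name),
    )
    classes = tuple(np.array(buckets[k], dtype=int) for k in order)

    # per-peptide balance: |class ∩ peptide| constant over peptides
    for k, members in zip(order, classes):
        counts = np.bincount(pep_of[members], minlength=n_peptides)
        if not np.all(counts == counts[0]):
            raise ValueError(f"class {k} is not balanced across peptides: {counts}")

    covered = np.concatenate(classes) if classes else np.empty(0, int)
    if len(np.unique(covered)) != len(atoms):
        raise AssertionError("equivalence classes do not form a partition")

    return EquivalencePartition(
        classes=classes,
        keys=tuple(order),
        n_atoms=len(atoms),
        n_peptides=n_peptides,
    )
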