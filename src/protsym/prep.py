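"""Preparation pipeline: make a raw PDB structure ready for CSM analysis.

A raw crystallographic file cannot be scored directly: it carries solvent
and ligand records, alternate conformations, sometimes hydrogens, and the
peptides of a homomer frequently differ in length because residues or
atoms are unresolved in some chains.  The CSM machinery requires every
peptide to carry the identical (residue, atom-name) sequence, so
preparation proceeds in two stages:

* :func:`clean` drops HETATM/solvent records, hydrogens (by default) and
  all but the first-listed alternate location of each atom;
* :func:`harmonize_chains` deletes, from *every* chain, any residue or atom
  missing from at least one chain (whether declared in REMARK 465/470 or
  detected by cross-chain comparison), then verifies that all peptides have
  identical length and identity sequence.

Both stages are idempotent and report what they removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .structures import Atom, EmptyStructureError, Peptide, Structure

__all__ = ["PrepReport", "clean", "harmonize_chains", "prepare", "NonProteinChainError"]

_SOLVENT_RESIDUES = frozenset({"HOH", "WAT", "DOD", "SOL", "H2O"})
_NUCLEIC_RESIDUES = frozenset({"A", "C", "G", "U", "I", "N", "DA", "DC", "DG", "DT", "DI", "DU"})
_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class NonProteinChainError(ValueError):
    """A chain contains nucleic-acid residues; such files are rejected."""


@dataclass
class PrepReport:
    """What preparation removed, and the final per-chain geometry."""

    removed_hetatm: int = 0
    removed_hydrogens: int = 0
    removed_altloc_atoms: int = 0
    removed_solvent: int = 0
    pruned_residues: list = field(default_factory=list)  # (residue_name, residue_seq, reason)
    pruned_atoms: list = field(default_factory=list)     # (chain, residue_seq, atom name)
    final_peptide_length: int = 0
    chains_kept: list = field(default_factory=list)

    def merged_with(self, other: "PrepReport") -> "PrepReport":
        return PrepReport(
            removed_hetatm=self.removed_hetatm + other.removed_hetatm,
            removed_hydrogens=self.removed_hydrogens + other.removed_hydrogens,
            removed_altloc_atoms=self.removed_altloc_atoms + other.removed_altloc_atoms,
            removed_solvent=self.removed_solvent + other.removed_solvent,
            pruned_residues=self.pruned_residues + other.pruned_residues,
            pruned_atoms=self.pruned_atoms + other.pruned_atoms,
            final_peptide_length=other.final_peptide_length or self.final_peptide_length,
            chains_kept=other.chains_kept or self.chains_kept,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_hetatm": self.removed_hetatm,
                "removed_hydrogens": self.removed_hydrogens,
                "removed_altloc_atoms": self.removed_altloc_atoms,
                "removed_solvent": self.removed_solvent,
                "pruned_residues": [list(t) for t in self.pruned_residues],
                "pruned_atoms": [list(t) for t in self.pruned_atoms],
                "final_peptide_length": self.final_peptide_length,
                "chains_kept": self.chains_kept,
            },
            indent=2,
        )

    def summary(self) -> str:
        return (
            f"removed: {self.removed_hetatm} HETATM, {self.removed_solvent} solvent, "
            f"{self.removed_hydrogens} hydrogens, {self.removed_altloc_atoms} altloc atoms; "
            f"pruned {len(self.pruned_residues)} residue positions and "
            f"{len(self.pruned_atoms)} atoms; kept chains "
            f"{','.join(self.chains_kept)} of {self.final_peptide_length} atoms each"
        )


def clean(
    structure: Structure,
    remove_hydrogens: bool = True,
    solvent_blocklist: frozenset[str] = _SOLVENT_RESIDUES,
) -> tuple[Structure, PrepReport]:
    """Drop ligands/solvent, hydrogens and non-first alternate locations.

    Rejects chains containing nucleic-acid residues.  Idempotent.
    """
    report = PrepReport()
    peptides = []
    for peptide in structure.peptides:
        kept: list[Atom] = []
        seen_names: set[tuple[int, str, str]] = set()
        resnames = {a.residue_name.upper() for a in peptide.atoms if not a.het}
        if resnames & _NUCLEIC_RESIDUES:
            raise NonProteinChainError(
                f"chain {peptide.chain_id} contains nucleic-acid residues "
                f"({sorted(resnames & _NUCLEIC_RESIDUES)}); not a protein homomer"
            )
        for a in peptide.atoms:
            if a.het:
                report.removed_hetatm += 1
                continue
            if a.residue_name.upper() in solvent_blocklist:
                report.removed_solvent += 1
                continue
            if remove_hydrogens and a.element.upper() in _HYDROGEN_ELEMENTS:
                report.removed_hydrogens += 1
                continue
            # alternate locations: keep the first-listed occurrence of each
            # atom name within a residue (a blank altloc can precede a 'B')
            key = (a.residue_seq, a.insertion_code, a.name)
            if key in seen_names:
                report.removed_altloc_atoms += 1
                continue
            seen_names.add(key)
            if a.alt_loc:
                a = replace(a, alt_loc="")
            kept.append(a)
        if kept:
            peptides.append(Peptide(peptide.chain_id, tuple(kept)))
    if not peptides:
        raise EmptyStructureError("no atoms left after cleaning")
    out = Structure(tuple(peptides), structure.source_id)
    report.chains_kept = [p.chain_id for p in peptides]
    report.final_peptide_length = len(peptides[0])
    return out, report


def harmonize_chains(
    structure: Structure,
    missing_residues: dict[str, list[tuple[int, str]]] | None = None,
    missing_atoms: dict[str, list[tuple[int, str, str]]] | None = None,
) -> tuple[Structure, PrepReport]:
    """Delete residues/atoms absent from any chain from *all* chains.

    Missing positions may be declared per chain (REMARK 465/470 style) and
    are always also detected by direct cross-chain comparison, so files
    stripped of their headers harmonize correctly too.  A residue position
    present with *different* residue names in two chains is irreconcilable
    and raises.  The output satisfies the prepared-structure invariant:
    identical (residue_name, residue_seq, atom name) sequences everywhere;
    atoms within each residue follow the first chain's order.
    """
    if structure.n_peptides < 2:
        raise ValueError("harmonize_chains needs at least two peptides")
    missing_residues = missing_residues or {}
    missing_atoms = missing_atoms or {}
    report = PrepReport()

    # per chain: ordered residue positions and their atoms
    per_chain: list[dict[tuple[int, str], list[Atom]]] = []
    for peptide in structure.peptides:
        residues: dict[tuple[int, str], list[Atom]] = {}
        for a in peptide.atoms:
            residues.setdefault(a.residue_key, []).append(a)
        per_chain.append(residues)

    all_positions = sorted({pos for residues in per_chain for pos in residues})

    # residue names must agree wherever a position is present
    name_at: dict[tuple[int, str], str] = {}
    for residues in per_chain:
        for pos, atoms in residues.items():
            name = atoms[0].residue_name
            prior = name_at.setdefault(pos, name)
            if prior != name:
                raise ValueError(
                    f"chains disagree at residue {pos[0]}{pos[1]}: {prior} vs {name}"
                )

    declared_missing = {
        pos for chain_list in missing_residues.values() for pos in chain_list
    }
    keep_positions = []
    for pos in all_positions:
        present_everywhere = all(pos in residues for residues in per_chain)
        if present_everywhere and pos not in declared_missing:
            keep_positions.append(pos)
        else:
            reason = "declared missing" if pos in declared_missing else "absent from some chain"
            report.pruned_residues.append((name_at[pos], pos[0], reason))

    declared_missing_atoms = {
        (pos_seq, icode, name)
        for chain_list in missing_atoms.values()
        for (pos_seq, icode, name) in chain_list
    }
    # common atom names per kept residue position (ordered by first chain)
    keep_atoms: dict[tuple[int, str], list[str]] = {}
    for pos in keep_positions:
        ref_order = [a.name for a in per_chain[0][pos]]
        common = set(ref_order)
        for residues in per_chain[1:]:
            common &= {a.name for a in residues[pos]}
        common -= {n for n in ref_order if (pos[0], pos[1], n) in declared_missing_atoms}
        keep_atoms[pos] = [n for n in ref_order if n in common]
        for ci, residues in enumerate(per_chain):
            for a in residues[pos]:
                if a.name not in common:
                    report.pruned_atoms.append(
                        (structure.peptides[ci].chain_id, pos[0], a.name)
                    )

    peptides = []
    for peptide, residues in zip(structure.peptides, per_chain):
        atoms: list[Atom] = []
        for pos in keep_positions:
            by_name = {a.name: a for a in residues[pos]}
            atoms.extend(by_name[n] for n in keep_atoms[pos])
        if not atoms:
            raise EmptyStructureError(
                f"chain {peptide.chain_id} is empty after harmonization"
            )
        peptides.append(Peptide(peptide.chain_id, tuple(atoms)))
    out = Structure(tuple(peptides), structure.source_id)
    if not out.is_prepared():
        raise AssertionError("harmonize_chains failed to equalize identity sequences")
    report.chains_kept = [p.chain_id for p in peptides]
    report.final_peptide_length = len(peptides[0])
    return out, report


def prepare(
    structure: Structure,
    remove_hydrogens: bool = True,
    missing_residues: dict[str, list[tuple[int, str]]] | None = None,
    missing_atoms: dict[str, list[tuple[int, str, str]]] | None = None,
) -> tuple[Structure, PrepReport]:
    """Full pipeline: clean, then harmonize across chains."""
    cleaned, rep1 = clean(structure, remove_hydrogens=remove_hydrogens)
    if cleaned.n_peptides < 2:
        raise ValueError("prepared structure must have at least two peptides")
    harmonized, rep2 = harmonize_chains(cleaned, missing_residues, missing_atoms)
    return harmonized, rep1.merged_with(rep2)
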