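import numpy as np
import pytest
from dataclasses import replace

from protsym import (
    Peptide,
    Structure,
    clean,
    harmonize_chains,
    prepare,
)
from protsym.prep import NonProteinChainError
from protsym.structures import EmptyStructureError

from conftest import build_chain, make_atom, ALA_ATOMS, VAL_ATOMS, GLY_ATOMS


def _with_extra_atoms(peptide, extra):
    return Peptide(peptide.chain_id, peptide.atoms + tuple(extra))


def test_altloc_keeps_first_listed(clean_dimer):
    a = clean_dimer.peptides[0]
    atoms = []
    for at in a.atoms:
        if at.name == "CB" and at.residue_seq == 1:
            # residue resolved in two conformations: A listed first, then B
            atoms.append(replace(at, alt_loc="A", serial=900))
            atoms.append(replace(at, alt_loc="B", serial=901,
                                 coords=(at.coords[0] + 1, at.coords[1], at.coords[2])))
        else:
            atoms.append(at)
    dirty = Structure((Peptide("A", tuple(atoms)), clean_dimer.peptides[1]))
    cleaned, report = clean(dirty)
    assert report.removed_altloc_atoms == 1
    kept = [at for at in cleaned.peptides[0].atoms if at.serial == 900]
    assert len(kept) == 1 and kept[0].alt_loc == ""
    assert not any(at.serial == 901 for at in cleaned.peptides[0].atoms)


def test_hydrogen_removal_counts(clean_dimer):
    a = clean_dimer.peptides[0]
    hydrogens = [
        make_atom(800 + i, f"H{i}", "H", "ALA", 1, "A", (float(i), 0, 0))
        for i in range(10)
    ]
    dirty = Structure((_with_extra_atoms(a, hydrogens), clean_dimer.peptides[1]))
    cleaned, report = clean(dirty, remove_hydrogens=True)
    assert report.removed_hydrogens == 10
    assert len(cleaned) == len(clean_dimer)
    kept, report2 = clean(dirty, remove_hydrogens=False)
    assert report2.removed_hydrogens == 0
    assert len(kept) == len(clean_dimer) + 10


def test_hetatm_and_solvent_removed(clean_dimer):
    a = clean_dimer.peptides[0]
    ligand = make_atom(850, "FE", "Fe", "HEM", 99, "A", (5, 5, 5), het=True)
    water = make_atom(851, "O", "O", "HOH", 100, "A", (6, 6, 6))
    dirty = Structure((_with_extra_atoms(a, [ligand, water]), clean_dimer.peptides[1]))
    cleaned, report = clean(dirty)
    assert report.removed_hetatm == 1
    assert report.removed_solvent == 1
    assert len(cleaned) == len(clean_dimer)


def test_clean_is_idempotent_on_clean_input(clean_dimer):
    cleaned, report = clean(clean_dimer)
    assert cleaned.coords.shape == clean_dimer.coords.shape
    assert report.removed_hetatm == report.removed_hydrogens == 0
    assert report.removed_altloc_atoms == report.removed_solvent == 0
    again, report2 = clean(cleaned)
    assert again.atoms == cleaned.atoms


def test_nucleic_chain_rejected(clean_dimer):
    dna = build_chain("C", [("DA", 1, [("P", "P", (0, 0, 0)), ("C1'", "C", (1, 0, 0))])])
    with pytest.raises(NonProteinChainError, match="chain C"):
        clean(Structure(clean_dimer.peptides + (dna,)))


def test_everything_removed_raises():
    water = build_chain("A", [("HOH", 1, [("O", "O", (0, 0, 0))])])
    with pytest.raises(EmptyStructureError):
        clean(Structure((water,)))


def test_missing_residue_deleted_from_all_chains():
    residues_a = [("ALA", 1, ALA_ATOMS), ("VAL", 2, VAL_ATOMS), ("GLY", 3, GLY_ATOMS)]
    residues_b = [("ALA", 1, ALA_ATOMS), ("GLY", 3, GLY_ATOMS)]  # VAL 2 unresolved
    s = Structure((build_chain("A", residues_a),
                   build_chain("B", residues_b, start_serial=100)))
    out, report = harmonize_chains(s)
    assert out.is_prepared()
    assert all(len(p) == len(ALA_ATOMS) + len(GLY_ATOMS) for p in out.peptides)
    assert ("VAL", 2, "absent from some chain") in report.pruned_residues
    assert not any(a.residue_seq == 2 for a in out.atoms)


def test_missing_atom_deleted_from_all_chains():
    full = [("ALA", 1, ALA_ATOMS), ("VAL", 2, VAL_ATOMS)]
    partial = [("ALA", 1, ALA_ATOMS), ("VAL", 2, VAL_ATOMS[:-1])]  # CG2 missing
    s = Structure((
        build_chain("A", full),
        build_chain("B", full, start_serial=100),
        build_chain("C", partial, start_serial=200),
    ))
    out, report = harmonize_chains(s)
    assert out.is_prepared()
    assert not any(a.name == "CG2" for a in out.atoms)
    assert ("A", 2, "CG2") in report.pruned_atoms and ("B", 2, "CG2") in report.pruned_atoms
    # ℓ × common-atom-multiset size exactly
    assert len(out) == 3 * (len(ALA_ATOMS) + len(VAL_ATOMS) - 1)


def test_declared_missing_residue_removed_even_if_present():
    residues = [("ALA", 1, ALA_ATOMS), ("GLY", 3, GLY_ATOMS)]
    s = Structure((build_chain("A", residues),
                   build_chain("B", residues, start_serial=100)))
    out, report = harmonize_chains(s, missing_residues={"B": [(3, "")]})
    assert not any(a.residue_seq == 3 for a in out.atoms)
    assert ("GLY", 3, "declared missing") in report.pruned_residues


def test_identical_chains_no_deletions(clean_dimer):
    out, report = harmonize_chains(clean_dimer)
    assert out.atoms == clean_dimer.atoms
    assert report.pruned_residues == [] and report.pruned_atoms == []
    # idempotent
    again, report2 = harmonize_chains(out)
    assert again.atoms == out.atoms


def test_irreconcilable_residue_name_raises():
    s = Structure((
        build_chain("A", [("ALA", 1, ALA_ATOMS)]),
        build_chain("B", [("GLY", 1, GLY_ATOMS)], start_serial=100),
    ))
    with pytest.raises(ValueError, match="residue 1"):
        harmonize_chains(s)


def test_prepare_pipeline_end_to_end(clean_dimer):
    a = clean_dimer.peptides[0]
    extra = [
        make_atom(900, "H", "H", "ALA", 1, "A", (0, 0, 9)),
        make_atom(901, "O", "O", "HOH", 50, "A", (9, 9, 9)),
    ]
    dirty = Structure((_with_extra_atoms(a, extra), clean_dimer.peptides[1]))
    out, report = prepare(dirty)
    assert out.is_prepared()
    assert report.removed_hydrogens == 1 and report.removed_solvent == 1
    assert report.final_peptide_length == len(clean_dimer.peptides[0])
    assert report.chains_kept == ["A", "B"]
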