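"""Domain model for multi-chain protein structures and fixed-width PDB I/O.

The coordinate workhorse of the package is :class:`Structure`: an ordered
list of peptides (chains), each an ordered list of :class:`Atom`.  A
*prepared* structure — one that went through :mod:`protsym.prep` — has the
additional guarantee that every peptide carries the identical
``(residue_name, residue_seq, atom name)`` sequence, which is what the
assignment machinery relies on.

PDB reading is deliberately minimal and strict: only fixed-width ``ATOM``
(optionally ``HETATM``) records are consumed, the first ``MODEL`` of a
multi-model file is used, and a malformed line raises
:class:`PDBParseError` carrying its line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Peptide",
    "Structure",
    "PDBParseError",
    "EmptyStructureError",
    "read_pdb",
    "parse_missing_remarks",
    "write_pdb",
    "centroid",
]


class PDBParseError(ValueError):
    """A fixed-width PDB record could not be parsed."""


class EmptyStructureError(ValueError):
    """An operation received or produced a structure without atoms."""


# Two-letter element symbols that legitimately occur in protein PDB files.
_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "NI", "CO", "CD",
}


def _element_from_name(raw_name: str) -> str:
    """Infer the element from a 4-character PDB atom-name field.

    In PDB v3.3 the element portion of the name is right-justified in the
    first two columns of the field: `` CA `` is an alpha carbon while
    ``CA  `` would be calcium.  Leading digits (as in ``1HB``) are skipped.
    """
    name = raw_name.ljust(4)
    head = name[:2].strip().lstrip("0123456789")
    if name[0] != " " and head.upper() in _TWO_LETTER_ELEMENTS:
        return head.upper().capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass(frozen=True)
class Atom:
    """One ATOM record: identity plus Cartesian coordinates in angstroms."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    coords: tuple[float, float, float]
    alt_loc: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r}: empty element")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name!r}: non-finite coords")

    @property
    def residue_key(self) -> tuple[int, str]:
        """Residue identity within a chain: (residue_seq, insertion_code)."""
        return (self.residue_seq, self.insertion_code)


@dataclass(frozen=True)
class Peptide:
    """A single chain: ordered atoms sharing one chain identifier."""

    chain_id: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.chain_id != self.chain_id:
                raise ValueError(
                    f"atom {a.serial} has chain {a.chain_id!r}, expected {self.chain_id!r}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def identity_sequence(self) -> tuple[tuple[str, int, str, str], ...]:
        """Per-atom (residue_name, residue_seq, insertion_code, atom name)."""
        return tuple(
            (a.residue_name, a.residue_seq, a.insertion_code, a.name) for a in self.atoms
        )


@dataclass(frozen=True)
class Structure:
    """An ordered collection of peptides, typically one homomer."""

    peptides: tuple[Peptide, ...]
    source_id: str = ""

    def __len__(self) -> int:
        return sum(len(p) for p in self.peptides)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return tuple(a for p in self.peptides for a in p.atoms)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an (N, 3) array in peptide order."""
        if len(self) == 0:
            return np.zeros((0, 3))
        return np.concatenate([p.coords for p in self.peptides], axis=0)

    def peptide_index_of_atom(self) -> np.ndarray:
        """For each flat atom index, the index of its peptide."""
        out = np.empty(len(self), dtype=int)
        k = 0
        for i, p in enumerate(self.peptides):
            out[k : k + len(p)] = i
            k += len(p)
        return out

    def peptide_slices(self) -> list[slice]:
        """Flat-index slice of each peptide, in order."""
        slices, k = [], 0
        for p in self.peptides:
            slices.append(slice(k, k + len(p)))
            k += len(p)
        return slices

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with coordinates replaced row-for-row."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError(f"expected coords of shape ({len(self)}, 3)")
        peptides = []
        k = 0
        for p in self.peptides:
            new_atoms = tuple(
                replace(a, coords=tuple(coords[k + j])) for j, a in enumerate(p.atoms)
            )
            peptides.append(Peptide(p.chain_id, new_atoms))
            k += len(p)
        return Structure(tuple(peptides), self.source_id)

    def is_prepared(self) -> bool:
        """True when all peptides share one identity sequence (equal length)."""
        if not self.peptides:
            return False
        ref = self.peptides[0].identity_sequence()
        ref_ids = tuple((r[0], r[1], r[2], r[3]) for r in ref)
        for p in self.peptides[1:]:
            seq = p.identity_sequence()
            if len(seq) != len(ref_ids):
                return False
            if tuple((r[0], r[1], r[2], r[3]) for r in seq) != ref_ids:
                return False
        return True


def _parse_atom_line(line: str, lineno: int, chain_fallback: str = "A") -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or chain_fallback
        residue_seq = int(line[22:26])
        insertion_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record: {line.rstrip()!r}") from exc
    element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(line[12:16])
    if not element:
        raise PDBParseError(f"line {lineno}: cannot determine element for {name!r}")
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_seq=residue_seq,
        insertion_code=insertion_code,
        chain_id=chain_id,
        coords=(x, y, z),
        alt_loc=alt_loc,
        het=line.startswith("HETATM"),
    )


def read_pdb(path: str | Path, include_hetatm: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only ``ATOM`` records (plus ``HETATM`` when *include_hetatm*) contribute
    atoms; ``ANISOU`` and other non-coordinate lines are ignored.  Of a
    multi-model file only the first ``MODEL`` is used.  Peptide order
    follows the file order of first appearance of each chain identifier.
    """
    path = Path(path)
    by_chain: dict[str, list[Atom]] = {}
    in_model = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                in_model += 1
                if in_model > 1:
                    break
                continue
            if rec.startswith("ENDMDL"):
                break
            if rec == "ATOM  " or (include_hetatm and rec == "HETATM"):
                atom = _parse_atom_line(line, lineno)
                by_chain.setdefault(atom.chain_id, []).append(atom)
    if not by_chain:
        raise EmptyStructureError(f"{path}: no ATOM records found")
    peptides = tuple(Peptide(cid, tuple(atoms)) for cid, atoms in by_chain.items())
    return Structure(peptides, source_id=path.stem)


def parse_missing_remarks(path: str | Path) -> tuple[dict[str, list[tuple[int, str]]], dict[str, list[tuple[int, str, str]]]]:
    """Extract REMARK 465 (missing residues) and 470 (missing atoms).

    Returns ``(missing_residues, missing_atoms)`` keyed by chain id:
    residues as ``(residue_seq, insertion_code)``; atoms as
    ``(residue_seq, insertion_code, atom_name)`` flattened per listed atom.
    Header-less files simply yield empty mappings.
    """
    missing_res: dict[str, list[tuple[int, str]]] = {}
    missing_atoms: dict[str, list[tuple[int, str, str]]] = {}

    def _seq(tok: str) -> tuple[int, str]:
        tok = tok.strip()
        if tok and tok[-1].isalpha():
            return int(tok[:-1]), tok[-1]
        return int(tok), ""

    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("REMARK 465"):
                fields = line[10:].split()
                # data lines look like: [model] RES C SSSEQI
                if len(fields) in (3, 4) and len(fields[-2]) == 1:
                    try:
                        seq, icode = _seq(fields[-1])
                    except ValueError:
                        continue
                    missing_res.setdefault(fields[-2], []).append((seq, icode))
            elif line.startswith("REMARK 470"):
                fields = line[10:].split()
                # data lines: [model] RES CSSEQI ATOMS...
                if len(fields) >= 3 and len(fields[0]) == 3 and fields[0].isalpha():
                    chain = fields[1][0]
                    try:
                        seq, icode = _seq(fields[1][1:])
                    except ValueError:
                        continue
                    for name in fields[2:]:
                        missing_atoms.setdefault(chain, []).append((seq, icode, name))
    return missing_res, missing_atoms


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-width ATOM records with a TER after each chain."""
    if len(structure) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    lines = []
    for peptide in structure.peptides:
        last = None
        for a in peptide.atoms:
            rec = "HETATM" if a.het else "ATOM  "
            x, y, z = a.coords
            lines.append(
                f"{rec}{a.serial:5d} {_format_atom_name(a.name, a.element)}"
                f"{a.alt_loc or ' '}{a.residue_name:>3s} {a.chain_id}"
                f"{a.residue_seq:4d}{a.insertion_code or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element.upper():>2s}"
            )
            last = a
        if last is not None:
            lines.append(
                f"TER   {last.serial + 1:5d}      {last.residue_name:>3s} "
                f"{last.chain_id}{last.residue_seq:4d}{last.insertion_code or ' '}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def centroid(structure: Structure | np.ndarray) -> np.ndarray:
    """Geometric (unweighted) center of mass Q0 = mean of all coordinates."""
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure, float)
    if coords.shape[0] == 0:
        raise EmptyStructureError("centroid of an empty structure")
    return coords.mean(axis=0)
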