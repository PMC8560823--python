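"""Coordinate data model: PDB reading/writing, selections, distances, sequences.

Conventions
-----------
* Coordinates are in Å and residue numbering follows the author numbering of
  the source file; no renumbering is ever performed implicitly.
* Alternate locations are resolved to the highest-occupancy conformer; on an
  occupancy tie the alphabetically first altloc id wins.
* Only the first MODEL of a multi-model file is ever considered, and
  multi-model (NMR-style) files are rejected outright.
* Insertion codes are carried on every residue identifier but never used for
  arithmetic; residue ranges compare ``(residue_number, insertion_code)``
  lexicographically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "SelectionSpec",
    "SequenceRecord",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "select",
    "extract_sequence",
    "apply_mutations",
    "distance",
]

MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Residue names treated as solvent and skipped by default.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def is_mainchain(self) -> bool:
        return self.atom_name in MAINCHAIN_ATOMS


@dataclass
class Structure:
    """A flat list of atoms; the substrate of every geometric operation."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.atoms == other.atoms

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[str, int, str]]:
        """Residue identifiers in file order (chain, number, insertion code)."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out


@dataclass(frozen=True)
class SelectionSpec:
    """Which atoms to keep: chains, inclusive residue ranges, atom classes."""

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_classes: str = "all"  # all | heavy | mainchain | sidechain

    def __post_init__(self):
        if self.atom_classes not in {"all", "heavy", "mainchain", "sidechain"}:
            raise ValueError(f"unknown atom class {self.atom_classes!r}")
        if self.residue_ranges is not None:
            for start, end in self.residue_ranges:
                if start > end:
                    raise ValueError(f"empty residue range ({start}, {end})")

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None:
            if not any(s <= atom.residue_number <= e for s, e in self.residue_ranges):
                return False
        if self.atom_classes == "heavy" and atom.element == "H":
            return False
        if self.atom_classes == "mainchain" and not atom.is_mainchain():
            return False
        if self.atom_classes == "sidechain" and atom.is_mainchain():
            return False
        return True


def spec(chains: Iterable[str] | None = None,
         residue_ranges: Iterable[tuple[int, int]] | None = None,
         atom_classes: str = "all") -> SelectionSpec:
    """Convenience constructor for :class:`SelectionSpec`."""
    return SelectionSpec(
        chains=frozenset(chains) if chains is not None else None,
        residue_ranges=tuple(tuple(r) for r in residue_ranges) if residue_ranges is not None else None,
        atom_classes=atom_classes,
    )


@dataclass(frozen=True)
class SequenceRecord:
    """A one-letter sequence with parallel author numbering."""

    id: str
    residues: str
    numbering: tuple[tuple[int, str], ...]

    def __post_init__(self):
        if len(self.residues) != len(self.numbering):
            raise ValueError(
                f"numbering length {len(self.numbering)} != sequence length {len(self.residues)}"
            )

    def position_index(self, residue_number: int, insertion_code: str = "") -> int:
        try:
            return self.numbering.index((residue_number, insertion_code))
        except ValueError:
            raise KeyError(f"position {residue_number}{insertion_code} not in record {self.id}")


class PDBParseError(ValueError):
    pass


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    # Strip leading digits (e.g. 1HB) then take the leading letter(s).
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "SE", "CL", "BR", "NA", "CA"}:
        # Two-letter elements only occur in HETATM metals/halogens; CA in a
        # polymer record is a carbon (alpha carbon) and is caught by the
        # caller passing residue context, so default to the single letter.
        pass
    return stripped[0].upper()


def read_pdb(source: str, *, include_het: bool = False, include_waters: bool = False) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is read; files containing more than one MODEL are
    rejected. Waters and (by default) heteroatoms are excluded. Alternate
    locations are resolved to the highest occupancy, ties broken by the
    alphabetically first altloc identifier.
    """
    lines = source.splitlines()
    model_count = 0
    atoms: list[Atom] = []
    # key -> (altloc, occupancy, Atom) of currently retained conformer
    altloc_seen: dict[tuple, tuple[str, float, int]] = {}

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            model_count += 1
            if model_count > 1:
                raise PDBParseError(
                    f"line {lineno}: multi-model file (second MODEL record); "
                    "only single-model structures are supported"
                )
            continue
        if rec == "ENDMDL":
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec.strip()} record")
        try:
            atom_name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip()
            res_num = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ = float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0
            bfac = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed fixed-width field ({exc})") from exc
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise PDBParseError(f"line {lineno}: non-finite coordinate")

        if res_name in WATER_NAMES and not include_waters:
            continue
        if (rec == "HETATM" and res_name != "MSE"
                and res_name not in WATER_NAMES and not include_het):
            continue
        if not element:
            element = _guess_element(atom_name)

        atom = Atom(chain_id, res_num, icode, res_name, atom_name, element,
                    (x, y, z), occ, bfac)
        key = (chain_id, res_num, icode, atom_name)
        if key in altloc_seen:
            prev_alt, prev_occ, prev_idx = altloc_seen[key]
            take = occ > prev_occ or (occ == prev_occ and (altloc or "~") < (prev_alt or "~"))
            if take:
                atoms[prev_idx] = atom
                altloc_seen[key] = (altloc, occ, prev_idx)
            continue
        altloc_seen[key] = (altloc, occ, len(atoms))
        atoms.append(atom)

    if not atoms:
        raise PDBParseError("no atoms parsed: empty model")
    return Structure(atoms)


def write_pdb(structure: Structure) -> str:
    """Serialise a structure back to PDB fixed-column text (3-decimal coords)."""
    out = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name
        # Standard PDB alignment: 1-3 letter names start in column 14 unless
        # the name is 4 characters long.
        fname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
        out.append(
            f"ATOM  {i % 100000:5d} {fname} {a.residue_name:>3s} {a.chain_id:1.1s}"
            f"{a.residue_number:4d}{a.insertion_code or ' ':1.1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
        )
    out.append("END")
    return "\n".join(out) + "\n"


def select(structure: Structure, selection: SelectionSpec) -> Structure:
    """Return the sub-structure matching ``selection``.

    An absent chain yields an empty selection with a warning, not an error.
    """
    if selection.chains is not None:
        present = set(structure.chains())
        missing = selection.chains - present
        if missing:
            warnings.warn(f"chains absent from structure: {sorted(missing)}", stacklevel=2)
    return Structure([a for a in structure.atoms if selection.matches(a)])


def extract_sequence(structure: Structure, chain: str) -> SequenceRecord:
    """One-letter sequence of a chain in residue-number order.

    Non-standard residues map to ``X``; author numbering is preserved.
    """
    residues: dict[tuple[int, str], str] = {}
    for a in structure.atoms:
        if a.chain_id != chain:
            continue
        key = (a.residue_number, a.insertion_code)
        residues.setdefault(key, THREE_TO_ONE.get(a.residue_name, "X"))
    ordered = sorted(residues)
    return SequenceRecord(
        id=chain,
        residues="".join(residues[k] for k in ordered),
        numbering=tuple(ordered),
    )


def apply_mutations(seq: SequenceRecord,
                    mutations: Sequence[tuple[str, int, str]]) -> SequenceRecord:
    """Apply point mutations ``(wild, position, new)`` to a sequence copy.

    Each stated wild-type letter must match the sequence at the stated author
    position; a mismatch raises, naming the position and the observed letter
    (this guards against numbering-offset mistakes).
    """
    letters = list(seq.residues)
    for wild, pos, new in mutations:
        idx = seq.position_index(pos)
        observed = letters[idx]
        if observed != wild:
            raise ValueError(
                f"wild-type mismatch at position {pos}: expected {wild}, found {observed}"
            )
        letters[idx] = new
    return SequenceRecord(seq.id, "".join(letters), seq.numbering)


def distance(a: Atom, b: Atom) -> float:
    """Euclidean distance between two atoms in Å."""
    return math.dist(a.position, b.position)


def parse_mutation(text: str) -> tuple[str, int, str]:
    """Parse the field's compact notation, e.g. ``"D682C"`` -> (D, 682, C)."""
    wild, new = text[0], text[-1]
    return wild, int(text[1:-1]), new
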