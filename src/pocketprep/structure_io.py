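"""Column-exact PDB reading/writing, TRIPOS MOL2 parsing, element guessing,
altLoc filtering and ligand-name extraction.

PDB files are read tolerantly (fixed columns first, whitespace fallback for
coordinate fields) and written with strict fixed columns, because the altLoc
logic downstream is column-based.  Atom order is preserved through read/write
round trips.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .elements import canonical_symbol, is_two_letter_symbol
from .errors import Mol2ParseError, PdbParseError

__all__ = [
    "AtomRecord",
    "Structure",
    "LigandSpec",
    "parse_pdb",
    "guess_elements",
    "filter_altloc",
    "extract_ligand_name",
    "parse_mol2",
    "write_pdb",
]

UNNAMED = "UNNAMED"


@dataclass
class AtomRecord:
    """A single ATOM/HETATM record.

    ``name_raw`` preserves the original 4-character name field (columns
    13-16) when the atom was read from a file; it is excluded from equality
    and only used to reproduce name justification on write and to guess
    elements by column position.
    """

    record_type: str = "ATOM"
    serial: int = 1
    atom_name: str = ""
    alt_loc: str = " "
    res_name: str = ""
    chain_id: str = " "
    res_seq: int = 1
    insertion_code: str = " "
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    element: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    name_raw: str = field(default="", compare=False, repr=False)

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        """Residue identity: (chain, number, insertion code, name)."""
        return (self.chain_id, self.res_seq, self.insertion_code, self.res_name)


@dataclass
class Structure:
    """Ordered atom collection plus an explicit bond list.

    Bonds are unordered serial pairs stored as sorted tuples; every endpoint
    must name an existing serial and self-bonds are rejected.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: set[tuple[int, int]] = field(default_factory=set)
    title: str = ""

    def __post_init__(self) -> None:
        serials = {a.serial for a in self.atoms}
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on serial {i}")
            if i not in serials or j not in serials:
                raise ValueError(f"bond ({i},{j}) references a missing serial")

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a) for a in self.atoms],
            bonds=set(self.bonds),
            title=self.title,
        )

    def coords_array(self):
        import numpy as np

        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def neighbors(self) -> dict[int, set[int]]:
        """Adjacency by serial."""
        nb: dict[int, set[int]] = {a.serial: set() for a in self.atoms}
        for i, j in self.bonds:
            nb[i].add(j)
            nb[j].add(i)
        return nb

    def subset(self, keep_serials: Iterable[int]) -> "Structure":
        """Atoms with the given serials (original order); bonds restricted."""
        keep = set(keep_serials)
        atoms = [replace(a) for a in self.atoms if a.serial in keep]
        bonds = {(i, j) for (i, j) in self.bonds if i in keep and j in keep}
        return Structure(atoms=atoms, bonds=bonds, title=self.title)


@dataclass
class LigandSpec:
    """A named small molecule with 3D coordinates."""

    name: str
    structure: Structure

    def __post_init__(self) -> None:
        if not self.name:
            self.name = UNNAMED


def _bond_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed {what} field {text!r}") from exc
    if not math.isfinite(value):
        raise PdbParseError(f"line {lineno}: non-finite {what} {text!r}")
    return value


def _atom_from_columns(line: str, lineno: int) -> AtomRecord:
    line = line.rstrip("\n")
    padded = line.ljust(80)
    try:
        serial = int(padded[6:11])
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed serial {padded[6:11]!r}") from exc
    x = _parse_float(padded[30:38], "x coordinate", lineno)
    y = _parse_float(padded[38:46], "y coordinate", lineno)
    z = _parse_float(padded[46:54], "z coordinate", lineno)
    occ_text = padded[54:60].strip()
    b_text = padded[60:66].strip()
    elem_text = padded[76:78].strip()
    element = ""
    if elem_text:
        sym = canonical_symbol(elem_text)
        if sym is None:
            warnings.warn(
                f"line {lineno}: unrecognized element symbol {elem_text!r}; left empty"
            )
        else:
            element = sym
    try:
        res_seq = int(padded[22:26])
    except ValueError:
        res_seq = 0
    return AtomRecord(
        record_type=padded[0:6].strip(),
        serial=serial,
        atom_name=padded[12:16].strip(),
        alt_loc=padded[16],
        res_name=padded[17:21].strip(),
        chain_id=padded[21],
        res_seq=res_seq,
        insertion_code=padded[26],
        x=x,
        y=y,
        z=z,
        element=element,
        occupancy=float(occ_text) if occ_text else 1.0,
        b_factor=float(b_text) if b_text else 0.0,
        name_raw=padded[12:16],
    )


def _atom_from_tokens(line: str, lineno: int) -> AtomRecord:
    """Whitespace fallback for drifted files: RECORD serial name res [chain]
    resseq x y z [...]."""
    tokens = line.split()
    floats = [t for t in tokens if _is_float(t)]
    if len(floats) < 3:
        raise PdbParseError(f"line {lineno}: cannot locate coordinates")
    # First run of >=3 consecutive float tokens is taken as x, y, z.
    for k in range(len(tokens) - 2):
        if all(_is_float(tokens[k + m]) for m in range(3)):
            x, y, z = (float(tokens[k + m]) for m in range(3))
            break
    else:  # pragma: no cover - guarded above
        raise PdbParseError(f"line {lineno}: cannot locate coordinates")
    try:
        serial = int(tokens[1])
    except (IndexError, ValueError) as exc:
        raise PdbParseError(f"line {lineno}: malformed serial") from exc
    name = tokens[2] if len(tokens) > 2 else ""
    res = tokens[3] if len(tokens) > 3 else ""
    return AtomRecord(
        record_type=tokens[0],
        serial=serial,
        atom_name=name,
        res_name=res,
        x=x,
        y=y,
        z=z,
    )


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return math.isfinite(float(token))


def parse_pdb(text: str) -> Structure:
    """Parse PDB text into a Structure.

    One AtomRecord per ATOM/HETATM line, in file order.  CONECT pairs are
    deduplicated into bonds; dangling CONECT references and self-bonds are
    dropped with a warning.  Duplicate serials are tolerated (kept, with a
    warning); CONECT references resolve against the set of seen serials.
    """
    atoms: list[AtomRecord] = []
    conect_pairs: set[tuple[int, int]] = set()
    seen_serials: set[int] = set()
    duplicate_serials: set[int] = set()

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            try:
                atom = _atom_from_columns(line, lineno)
            except PdbParseError:
                if "." not in line[30:54]:
                    atom = _atom_from_tokens(line, lineno)
                else:
                    raise
            if atom.serial in seen_serials:
                duplicate_serials.add(atom.serial)
            seen_serials.add(atom.serial)
            atoms.append(atom)
        elif record == "CONECT":
            fields = line[6:].split()
            try:
                serials = [int(f) for f in fields]
            except ValueError:
                warnings.warn(f"line {lineno}: malformed CONECT record skipped")
                continue
            if len(serials) >= 2:
                center = serials[0]
                for partner in serials[1:]:
                    if partner != center:
                        conect_pairs.add(_bond_pair(center, partner))

    if duplicate_serials:
        warnings.warn(
            f"duplicate atom serials kept: {sorted(duplicate_serials)}; "
            "atoms are re-identified internally by position"
        )

    bonds = set()
    for i, j in conect_pairs:
        if i in seen_serials and j in seen_serials:
            bonds.add((i, j))
        else:
            warnings.warn(f"CONECT ({i},{j}) references a missing serial; dropped")
    return Structure(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# Element guessing
# ---------------------------------------------------------------------------

def _conventional_name_field(atom: AtomRecord) -> str:
    """Reconstruct the 4-character name field for atoms built in memory."""
    if atom.name_raw and len(atom.name_raw) == 4:
        return atom.name_raw
    name = atom.atom_name
    if len(name) >= 4:
        return name[:4]
    if name and (name[0].isdigit() or len(atom.element) == 2):
        return f"{name:<4}"
    return f" {name:<3}"


def guess_element_from_name(name_field: str) -> str:
    """Infer an element from a PDB atom-name field (columns 13-16).

    Two-letter symbols are recognized only when left-justified into column 13
    (PDB convention distinguishing ' CA ' alpha carbon from 'CA  ' calcium);
    leading digits are stripped; falls back to the first letter.
    """
    raw = name_field.ljust(4)[:4]
    stripped = raw.strip().lstrip("0123456789'\"*")
    if not stripped:
        return ""
    if raw[0] not in (" ",) and not raw[0].isdigit():
        two = raw[0:2].strip()
        if len(two) == 2 and is_two_letter_symbol(two):
            return canonical_symbol(two)  # type: ignore[return-value]
    sym = canonical_symbol(stripped[0])
    return sym or ""


def guess_elements(s: Structure) -> Structure:
    """Fill empty element fields from atom names; never touches set elements."""
    out = s.copy()
    for atom in out.atoms:
        if atom.element:
            continue
        guessed = guess_element_from_name(_conventional_name_field(atom))
        if guessed:
            atom.element = guessed
        else:
            warnings.warn(
                f"could not infer element for atom serial {atom.serial} "
                f"named {atom.atom_name!r}; element left empty"
            )
    return out


# ---------------------------------------------------------------------------
# altLoc filtering
# ---------------------------------------------------------------------------

def filter_altloc(s: Structure, keep_altloc: str = "A") -> Structure:
    """Keep atoms whose altLoc is blank or equals ``keep_altloc``.

    Atoms present only under a different altLoc are dropped (with a warning),
    reproducing the column-17 rule faithfully.
    """
    kept: list[AtomRecord] = []
    dropped: list[AtomRecord] = []
    for atom in s.atoms:
        if atom.alt_loc in (" ", "", keep_altloc):
            kept.append(replace(atom))
        else:
            dropped.append(atom)
    if dropped:
        surviving_keys = {(a.residue_id, a.atom_name) for a in kept}
        lost = [
            d for d in dropped if (d.residue_id, d.atom_name) not in surviving_keys
        ]
        if lost:
            warnings.warn(
                f"{len(lost)} atom(s) present only under altLoc != "
                f"{keep_altloc!r} were dropped entirely"
            )
    keep_serials = {a.serial for a in kept}
    bonds = {(i, j) for (i, j) in s.bonds if i in keep_serials and j in keep_serials}
    return Structure(atoms=kept, bonds=bonds, title=s.title)


# ---------------------------------------------------------------------------
# MOL2
# ---------------------------------------------------------------------------

def _mol2_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>"):
            name = line.strip()[len("@<TRIPOS>"):].upper()
            current = sections.setdefault(name, [])
        elif current is not None:
            current.append(line)
    return sections


def _valid_ligand_name(name: str) -> bool:
    name = name.strip()
    return bool(name) and name.upper() != UNNAMED and set(name) != {"*"}


def extract_ligand_name(mol2_text: str) -> str:
    """Ligand name with two fallbacks: the SUBSTRUCTURE line, then the
    substructure-name column of the ATOM section, else ``"UNNAMED"`` plus a
    warning.  Total: always returns a non-empty string."""
    sections = _mol2_sections(mol2_text)

    for line in sections.get("SUBSTRUCTURE", []):
        tokens = line.split()
        if not tokens:
            continue
        candidate = tokens[1] if len(tokens) >= 2 else tokens[0]
        if _valid_ligand_name(candidate):
            return candidate.strip()
        break  # only the line immediately following the header counts

    for line in sections.get("ATOM", []):
        tokens = line.split()
        if len(tokens) >= 8 and _valid_ligand_name(tokens[7]):
            return tokens[7].strip()
        if tokens:
            break

    warnings.warn("no usable ligand name in MOL2; falling back to 'UNNAMED'")
    return UNNAMED


def parse_mol2(mol2_text: str) -> LigandSpec:
    """Parse a TRIPOS MOL2 into a LigandSpec (coordinates + bond graph).

    Partial charges in the ATOM section are ignored for geometry.
    """
    sections = _mol2_sections(mol2_text)
    if "ATOM" not in sections or not any(l.split() for l in sections["ATOM"]):
        raise Mol2ParseError("MOL2 text has no @<TRIPOS>ATOM section")

    name = extract_ligand_name(mol2_text)
    atoms: list[AtomRecord] = []
    for line in sections["ATOM"]:
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) < 6:
            raise Mol2ParseError(f"short MOL2 atom line: {line!r}")
        atom_id = int(tokens[0])
        atom_name = tokens[1]
        x, y, z = (float(tokens[k]) for k in (2, 3, 4))
        sybyl = tokens[5]
        element = canonical_symbol(sybyl.split(".")[0]) or ""
        if not element:
            element = guess_element_from_name(f"{atom_name:<4}"[:4])
        res_seq = int(tokens[6]) if len(tokens) >= 7 and tokens[6].isdigit() else 1
        atoms.append(
            AtomRecord(
                record_type="HETATM",
                serial=atom_id,
                atom_name=atom_name,
                res_name=name,
                res_seq=res_seq,
                x=x,
                y=y,
                z=z,
                element=element,
            )
        )

    serials = {a.serial for a in atoms}
    bonds: set[tuple[int, int]] = set()
    for line in sections.get("BOND", []):
        tokens = line.split()
        if len(tokens) >= 3:
            i, j = int(tokens[1]), int(tokens[2])
            if i != j and i in serials and j in serials:
                bonds.add(_bond_pair(i, j))

    title = ""
    molecule = [l for l in sections.get("MOLECULE", []) if l.strip()]
    if molecule:
        title = molecule[0].strip()
    return LigandSpec(name=name, structure=Structure(atoms=atoms, bonds=bonds, title=title))


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(atom: AtomRecord, serial: int) -> str:
    name_field = _conventional_name_field(atom)
    res = atom.res_name
    res_field = f"{res[:4]:<4}" if len(res) >= 4 else f"{res:>3} "
    alt = atom.alt_loc if atom.alt_loc else " "
    icode = atom.insertion_code if atom.insertion_code else " "
    chain = atom.chain_id if atom.chain_id else " "
    element_field = f"{atom.element.upper():>2}" if atom.element else "  "
    return (
        f"{atom.record_type:<6}{serial:>5} {name_field}{alt[0]}{res_field}"
        f"{chain[0]}{atom.res_seq:>4}{icode[0]}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          {element_field}"
    )


def write_pdb(s: Structure, path: str | Path | None = None) -> str:
    """Render a Structure as fixed-column PDB text (optionally writing it).

    Serials above 99999 force a contiguous renumbering (warned); CONECT
    records are emitted for all bonds, partners sorted, four per line.
    """
    lines: list[str] = []
    serial_map: dict[int, int] = {}
    renumber = any(a.serial > 99999 or a.serial < 1 for a in s.atoms)
    if renumber and s.atoms:
        warnings.warn("atom serial out of PDB range; renumbering from 1")
    for idx, atom in enumerate(s.atoms, start=1):
        serial = idx if renumber else atom.serial
        serial_map[atom.serial] = serial
        lines.append(_format_atom_line(atom, serial))

    by_center: dict[int, list[int]] = {}
    for i, j in sorted(s.bonds):
        by_center.setdefault(serial_map.get(i, i), []).append(serial_map.get(j, j))
        by_center.setdefault(serial_map.get(j, j), []).append(serial_map.get(i, i))
    for center in sorted(by_center):
        partners = sorted(by_center[center])
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            lines.append("CONECT" + f"{center:>5}" + "".join(f"{p:>5}" for p in chunk))

    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
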