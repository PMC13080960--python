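"""Pocket cleanup and charging: dehydrogenation, distance-based bond
perception, connected-residue filtering, pluggable pH protonation, merging
with the ligand, and formal-charge bookkeeping.

The enforced order is dehydrogenate -> perceive connectivity -> drop
unconnected residues -> protonate, so hydrogens are only placed on the final
retained heavy-atom skeleton.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

import numpy as np

from .config import PipelineConfig
from .elements import COVALENT_RADII, DEFAULT_VALENCE, HYPERVALENT
from .errors import ProtonationError, ValenceError
from .structure_io import AtomRecord, LigandSpec, Structure, parse_pdb, write_pdb

__all__ = [
    "ResidueGraph",
    "ChargeReport",
    "strip_hydrogens",
    "perceive_bonds",
    "build_residue_graph",
    "filter_connected_residues",
    "protonate",
    "merge",
    "compute_formal_charge",
    "ProtonationBackend",
    "OpenBabelBackend",
    "SimpleGeometricBackend",
    "StubProtonationBackend",
]

BOND_TOLERANCE = 0.45  # added to the covalent-radius sum
MIN_BOND_DISTANCE = 0.4  # guard against coincident atoms

ResidueId = tuple[str, int, str, str]


@dataclass
class ResidueGraph:
    """Residues as nodes, inter-residue covalent bonds as edges."""

    nodes: set[ResidueId]
    edges: set[tuple[ResidueId, ResidueId]]

    def degree(self, residue: ResidueId) -> int:
        return sum(1 for e in self.edges if residue in e)


@dataclass
class ChargeReport:
    total_formal_charge: int
    per_residue: dict[ResidueId, int]
    per_atom: dict[int, int]


def strip_hydrogens(s: Structure) -> Structure:
    """Remove all hydrogen atoms and their bonds; heavy-atom order kept."""
    heavy = [replace(a) for a in s.atoms if a.element not in ("H", "D")]
    keep = {a.serial for a in heavy}
    bonds = {(i, j) for (i, j) in s.bonds if i in keep and j in keep}
    return Structure(atoms=heavy, bonds=bonds, title=s.title)


def perceive_bonds(s: Structure, tolerance: float = BOND_TOLERANCE) -> Structure:
    """Add a bond wherever the interatomic distance is at most the sum of
    covalent radii plus ``tolerance``; existing bonds are kept.

    Atoms with unknown elements (no radius entry) are excluded from
    perception with a warning, never a hard failure.
    """
    out = s.copy()
    known = [a for a in out.atoms if a.element in COVALENT_RADII]
    unknown = [a for a in out.atoms if a.element not in COVALENT_RADII]
    if unknown:
        warnings.warn(
            "atoms excluded from bond perception (unknown element): "
            f"{sorted(a.serial for a in unknown)}"
        )
    if len(known) < 2:
        return out
    xyz = np.array([[a.x, a.y, a.z] for a in known])
    radii = np.array([COVALENT_RADII[a.element] for a in known])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    cutoff = radii[:, None] + radii[None, :] + tolerance
    ii, jj = np.nonzero((dist <= cutoff) & (dist >= MIN_BOND_DISTANCE))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i < j:
            si, sj = known[i].serial, known[j].serial
            out.bonds.add((si, sj) if si < sj else (sj, si))
    return out


def build_residue_graph(s: Structure) -> ResidueGraph:
    """Edges between distinct residues sharing at least one covalent bond."""
    by_serial = {a.serial: a for a in s.atoms}
    nodes = {a.residue_id for a in s.atoms}
    edges: set[tuple[ResidueId, ResidueId]] = set()
    for i, j in s.bonds:
        ri, rj = by_serial[i].residue_id, by_serial[j].residue_id
        if ri != rj:
            edges.add((ri, rj) if ri <= rj else (rj, ri))
    return ResidueGraph(nodes=nodes, edges=edges)


def filter_connected_residues(s: Structure) -> Structure:
    """Keep only residues with at least one covalent link to another residue."""
    graph = build_residue_graph(s)
    connected = {r for edge in graph.edges for r in edge}
    kept = [a for a in s.atoms if a.residue_id in connected]
    if s.atoms and not kept:
        warnings.warn(
            "ALL residues are isolated (no inter-residue covalent bond); "
            "the connected-residue filter removed the entire structure"
        )
    keep_serials = {a.serial for a in kept}
    bonds = {(i, j) for (i, j) in s.bonds if i in keep_serials and j in keep_serials}
    return Structure(atoms=[replace(a) for a in kept], bonds=bonds, title=s.title)


# ---------------------------------------------------------------------------
# Protonation backends
# ---------------------------------------------------------------------------

class ProtonationBackend(Protocol):
    """Contract: return the structure with hydrogens added per a pH model;
    heavy atoms must be unchanged and keep their order."""

    def add_hydrogens(self, s: Structure, pH: float) -> Structure: ...


_H_DIRECTIONS = [
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (-1.0, 0.0, 0.0),
]


def _append_hydrogens(s: Structure, counts: dict[int, int], bond_length: float = 0.97) -> Structure:
    """Append ``counts[serial]`` hydrogens per heavy atom, bonded, at fixed
    deterministic offsets (directions cycle through a small table, pushed
    away from the mean neighbor direction when neighbors exist)."""
    out = s.copy()
    nb = out.neighbors()
    by_serial = {a.serial: a for a in out.atoms}
    next_serial = max((a.serial for a in out.atoms), default=0) + 1
    new_atoms: list[AtomRecord] = []
    new_bonds: set[tuple[int, int]] = set()
    for atom in s.atoms:
        n_h = counts.get(atom.serial, 0)
        if n_h <= 0:
            continue
        neighbor_coords = [
            np.array(by_serial[p].coords) for p in sorted(nb[atom.serial]) if p in by_serial
        ]
        center = np.array(atom.coords)
        if neighbor_coords:
            away = center - np.mean(neighbor_coords, axis=0)
            norm = np.linalg.norm(away)
            away = away / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        else:
            away = np.array([1.0, 0.0, 0.0])
        for k in range(n_h):
            direction = 0.6 * away + 0.8 * np.array(_H_DIRECTIONS[k % len(_H_DIRECTIONS)])
            direction = direction / np.linalg.norm(direction)
            pos = center + bond_length * direction
            h = AtomRecord(
                record_type=atom.record_type,
                serial=next_serial,
                atom_name=f"H{len(new_atoms) + 1}",
                res_name=atom.res_name,
                chain_id=atom.chain_id,
                res_seq=atom.res_seq,
                insertion_code=atom.insertion_code,
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
                element="H",
            )
            new_atoms.append(h)
            pair = (atom.serial, next_serial)
            new_bonds.add(pair if pair[0] < pair[1] else (pair[1], pair[0]))
            next_serial += 1
    out.atoms.extend(new_atoms)
    out.bonds |= new_bonds
    return out


@dataclass
class StubProtonationBackend:
    """Deterministic test backend: adds a fixed per-element hydrogen count
    (default O->2, N->1) regardless of environment.  No pH model."""

    counts_by_element: dict[str, int] | None = None

    def add_hydrogens(self, s: Structure, pH: float) -> Structure:
        table = self.counts_by_element or {"O": 2, "N": 1}
        counts = {a.serial: table.get(a.element, 0) for a in s.atoms}
        return _append_hydrogens(s, counts)


@dataclass
class SimpleGeometricBackend:
    """Valence-filling fallback backend: adds default_valence - degree
    hydrogens to each heavy atom.  pH-naive (no pKa model) - a warning is
    issued once per call so users know acid/base states are not adjusted."""

    def add_hydrogens(self, s: Structure, pH: float) -> Structure:
        warnings.warn(
            "SimpleGeometricBackend fills valences only and ignores pH "
            f"({pH}); install an external protonation tool for pKa-aware states"
        )
        work = s if s.bonds else perceive_bonds(s)
        nb = work.neighbors()
        counts: dict[int, int] = {}
        for atom in work.atoms:
            valence = DEFAULT_VALENCE.get(atom.element)
            if valence is None:
                continue
            if atom.element in HYPERVALENT:
                allowed = [v for v in HYPERVALENT[atom.element] if v >= len(nb[atom.serial])]
                valence = min(allowed) if allowed else len(nb[atom.serial])
            counts[atom.serial] = max(valence - len(nb[atom.serial]), 0)
        return _append_hydrogens(work, counts)


@dataclass
class OpenBabelBackend:
    """Default production backend: shells out to Open Babel (`obabel -p`)."""

    executable: str = "obabel"

    def add_hydrogens(self, s: Structure, pH: float) -> Structure:
        exe = shutil.which(self.executable)
        if exe is None:
            raise ProtonationError(
                f"protonation requires {self.executable!r} on PATH "
                "(Open Babel); install it or pass a different backend"
            )
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.pdb"
            outp = Path(tmp) / "out.pdb"
            write_pdb(s, inp)
            proc = subprocess.run(
                [exe, str(inp), "-O", str(outp), "-p", str(pH)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0 or not outp.exists():
                raise ProtonationError(
                    f"{self.executable} failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip()[-500:]}"
                )
            return parse_pdb(outp.read_text())


def protonate(s: Structure, pH: float, backend: ProtonationBackend | None = None) -> Structure:
    """Add hydrogens via the given backend (default: Open Babel)."""
    backend = backend or OpenBabelBackend()
    return backend.add_hydrogens(s, pH)


# ---------------------------------------------------------------------------
# Merge and formal charge
# ---------------------------------------------------------------------------

def merge(pocket: Structure, ligand: LigandSpec) -> Structure:
    """Concatenate pocket then ligand, serials renumbered from 1.

    Ligand atoms carry the ligand name as residue name; a clash with a pocket
    residue name gets a suffixed name plus a warning.
    """
    lig_name = ligand.name
    pocket_res_names = {a.res_name for a in pocket.atoms}
    if lig_name in pocket_res_names:
        warnings.warn(
            f"ligand name {lig_name!r} collides with a pocket residue name; "
            f"using {lig_name + '2'!r}"
        )
        lig_name = lig_name + "2"

    atoms: list[AtomRecord] = []
    serial_map_pocket: dict[int, int] = {}
    for idx, atom in enumerate(pocket.atoms, start=1):
        serial_map_pocket[atom.serial] = idx
        atoms.append(replace(atom, serial=idx))
    lig_res_seq = max((a.res_seq for a in pocket.atoms), default=0) + 1
    offset = len(pocket.atoms)
    serial_map_lig: dict[int, int] = {}
    for k, atom in enumerate(ligand.structure.atoms, start=1):
        serial_map_lig[atom.serial] = offset + k
        atoms.append(
            replace(
                atom,
                serial=offset + k,
                record_type="HETATM",
                res_name=lig_name,
                res_seq=lig_res_seq,
                insertion_code=" ",
                name_raw="",
            )
        )
    bonds: set[tuple[int, int]] = set()
    for i, j in pocket.bonds:
        a, b = serial_map_pocket[i], serial_map_pocket[j]
        bonds.add((a, b) if a < b else (b, a))
    for i, j in ligand.structure.bonds:
        a, b = serial_map_lig[i], serial_map_lig[j]
        bonds.add((a, b) if a < b else (b, a))
    return Structure(atoms=atoms, bonds=bonds, title=pocket.title)


def _target_valence(element: str, degree: int) -> int | None:
    base = DEFAULT_VALENCE.get(element)
    if base is None:
        return None
    if element in HYPERVALENT:
        allowed = [v for v in HYPERVALENT[element] if v >= degree]
        return min(allowed) if allowed else None
    return base


def compute_formal_charge(s: Structure, strict: bool = False) -> ChargeReport:
    """Formal charges by valence bookkeeping on the explicit bond graph.

    Pi bonds are assigned greedily between valence-deficient neighbors
    (terminal atoms first, which forces carbonyl/carboxylate patterns);
    leftover deficits on N/O/S become negative charges, over-coordinated
    N/O become positive.  Metals and unknown elements default to 0 with a
    warning.  In ``strict`` mode an unresolvable valence raises
    :class:`ValenceError` listing the offending atom serials.
    """
    nb = s.neighbors()
    charges: dict[int, int] = {a.serial: 0 for a in s.atoms}
    deficit: dict[int, int] = {}
    offending: list[int] = []
    unknown: list[int] = []

    heavy = [a for a in s.atoms if a.element != "H"]
    for atom in heavy:
        degree = len(nb[atom.serial])
        target = _target_valence(atom.element, degree)
        if target is None:
            unknown.append(atom.serial)
            deficit[atom.serial] = 0
            continue
        if degree > target:
            # Over-coordination: +1 for quaternary N / ternary O, else invalid.
            if atom.element == "N" and degree == 4:
                charges[atom.serial] = 1
                deficit[atom.serial] = 0
            elif atom.element == "O" and degree == 3:
                charges[atom.serial] = 1
                deficit[atom.serial] = 0
            else:
                offending.append(atom.serial)
                deficit[atom.serial] = 0
        else:
            deficit[atom.serial] = target - degree

    # Greedy pi-bond pairing; atoms with the fewest deficient partners first.
    def eligible_partners(serial: int) -> list[int]:
        return [p for p in sorted(nb[serial]) if deficit.get(p, 0) > 0]

    changed = True
    while changed:
        changed = False
        order = sorted(
            (a.serial for a in heavy if deficit.get(a.serial, 0) > 0),
            key=lambda sn: (len(eligible_partners(sn)), sn),
        )
        for serial in order:
            if deficit.get(serial, 0) <= 0:
                continue
            partners = eligible_partners(serial)
            if not partners:
                continue
            partner = max(partners, key=lambda p: (deficit[p], -p))
            deficit[serial] -= 1
            deficit[partner] -= 1
            changed = True

    by_serial = {a.serial: a for a in s.atoms}
    for serial, remaining in deficit.items():
        if remaining <= 0:
            continue
        element = by_serial[serial].element
        if element in ("O", "S", "N"):
            charges[serial] = -remaining
        else:
            offending.append(serial)

    if unknown:
        warnings.warn(
            f"formal charge defaulted to 0 for unknown/metal atoms: {sorted(unknown)}"
        )
    if offending:
        if strict:
            raise ValenceError(
                f"invalid valence at atom serial(s) {sorted(set(offending))}"
            )
        warnings.warn(
            "valence bookkeeping could not neutralize atom serial(s) "
            f"{sorted(set(offending))}; their formal charge defaults to 0"
        )

    per_residue: dict[ResidueId, int] = {}
    for atom in s.atoms:
        per_residue.setdefault(atom.residue_id, 0)
        per_residue[atom.residue_id] += charges[atom.serial]
    return ChargeReport(
        total_formal_charge=sum(charges.values()),
        per_residue=per_residue,
        per_atom=charges,
    )
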