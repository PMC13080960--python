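"""Deterministic synthetic protein-ligand complexes and an explicit-loop
pocket oracle.

``make_complex`` builds a ligand (compact carbon lattice) and protein shells
whose atoms sit at exact, controlled minimum distances from the ligand, with
optional pathologies injected: altLoc A/B duplicates, blank element columns,
isolated stray atoms, floating single residues, and waters.  Everything is a
pure function of the spec (same seed -> byte-identical files).

``brute_force_pocket`` re-implements the extraction rules with naive
all-pairs Python loops and is the independent oracle the vectorized
implementation must match exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .config import PipelineConfig
from .errors import FixtureError, LigandSizeError
from .structure_io import (
    AtomRecord,
    LigandSpec,
    Structure,
    filter_altloc,
    guess_elements,
    parse_mol2,
    parse_pdb,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_ligand_mol2",
    "make_complex",
    "brute_force_pocket",
    "random_fixture_spec",
]

_RES_NAMES = ("ALA", "GLY", "SER", "VAL", "THR", "LEU")
_ATOM_CYCLE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
_ATOMS_PER_RESIDUE = 4
_CHAIN_SPACING = (1.25, 1.72)  # accepted consecutive-atom distances
_CLEARANCE = 1.8  # minimum distance to unrelated atoms
_ISOLATION_CLEARANCE = 2.85  # stray atoms must stay beyond the 2.6 cap reach


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complex."""

    seed: int
    n_shell_atoms_by_radius: Mapping[float, int] = field(
        default_factory=lambda: {3.0: 72}
    )
    ligand_atom_count: int = 12
    n_altloc_pairs: int = 0
    n_isolated_atoms: int = 0
    n_waters: int = 0
    n_disconnected_residues: int = 0
    n_blank_elements: int = 0
    ligand_name: str = "LIG"


@dataclass
class GroundTruth:
    """Expected pocket under the extraction rules, computed by the oracle."""

    pocket_serials: tuple[int, ...]
    final_radius: float
    iterations_used: int
    expansion_exhausted: bool
    n_protein_atoms: int
    shell_serials_by_radius: dict[float, tuple[int, ...]]


# ---------------------------------------------------------------------------
# Ligand
# ---------------------------------------------------------------------------

def _ligand_coords(n: int, spacing: float = 1.5) -> np.ndarray:
    """First n points of a cubic lattice sorted by distance from the origin."""
    if n < 0:
        raise FixtureError("negative ligand atom count")
    span = range(-3, 4)
    points = sorted(
        ((i, j, k) for i in span for j in span for k in span),
        key=lambda p: (p[0] ** 2 + p[1] ** 2 + p[2] ** 2, p),
    )
    if n > len(points):
        raise FixtureError(f"ligand of {n} atoms exceeds the lattice capacity")
    return np.array(points[:n], dtype=float) * spacing


def _ligand_bonds(coords: np.ndarray, max_degree: int = 4) -> list[tuple[int, int]]:
    """Bond lattice neighbors (spacing distance), capping per-atom degree."""
    bonds: list[tuple[int, int]] = []
    degree = [0] * len(coords)
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if degree[i] >= max_degree or degree[j] >= max_degree:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= 1.51:
                bonds.append((i + 1, j + 1))
                degree[i] += 1
                degree[j] += 1
    return bonds


def make_ligand_mol2(
    n_atoms: int, name: str = "LIG", substructure_name: str | None = None
) -> str:
    """A compact all-carbon ligand with valid TRIPOS MOL2 sections."""
    coords = _ligand_coords(n_atoms)
    bonds = _ligand_bonds(coords)
    sub = substructure_name if substructure_name is not None else name
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{n_atoms:>5} {len(bonds):>5} {1:>5} 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for k, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"{k:>7} C{k:<3} {x:>12.4f} {y:>12.4f} {z:>12.4f} C.3 "
            f"{1:>4} {sub:<4} {0.0:>10.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(bonds, start=1):
        lines.append(f"{k:>6} {i:>5} {j:>5} 1")
    lines.append("@<TRIPOS>SUBSTRUCTURE")
    lines.append(f"{1:>6} {sub:<4} {1:>5} RESIDUE")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Controlled-distance placement
# ---------------------------------------------------------------------------

def _radial_positions(
    units: np.ndarray, ligand_xyz: np.ndarray, d: float
) -> np.ndarray:
    """For each unit direction, the point ``s*u`` whose minimum distance to
    the ligand equals d (NaN rows where the ray misses the d-surface)."""
    dots = units @ ligand_xyz.T  # (k, m)
    norms_sq = (ligand_xyz * ligand_xyz).sum(axis=1)  # (m,)
    disc = d * d - norms_sq[None, :] + dots * dots
    with np.errstate(invalid="ignore"):
        s_candidates = np.where(disc >= 0.0, dots + np.sqrt(np.maximum(disc, 0.0)), -np.inf)
    s = s_candidates.max(axis=1)
    points = s[:, None] * units
    bad = ~np.isfinite(s) | (s <= 0.0)
    # Verify the achieved minimum distance (rays grazing several atoms can
    # undershoot when the argmax atom is not the nearest).
    diff = points[:, None, :] - ligand_xyz[None, :, :]
    actual = np.sqrt((diff * diff).sum(axis=-1)).min(axis=1)
    bad |= np.abs(actual - d) > 1e-6
    points[bad] = np.nan
    return points


def _random_units(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    return v / norms


class _Placer:
    """Rejection-sampling placement of protein atoms at exact ligand
    min-distances, with clearance constraints.  Candidates are generated and
    filtered in vectorized batches."""

    _BATCH = 256

    def __init__(self, rng: np.random.Generator, ligand_xyz: np.ndarray):
        self.rng = rng
        self.ligand_xyz = ligand_xyz
        self._placed = np.zeros((0, 3))
        # (center, radius) keep-away zones around stray atoms placed early so
        # later chains cannot crowd them and break their isolation.
        self.exclusion_zones: list[tuple[np.ndarray, float]] = []

    @property
    def placed(self) -> np.ndarray:
        return self._placed

    def _accept(self, p: np.ndarray) -> np.ndarray:
        self._placed = np.vstack([self._placed, p[None, :]])
        return self._placed[-1]

    def _min_dists_to_placed(
        self, points: np.ndarray, exclude_last: int = 0
    ) -> np.ndarray:
        ref = self._placed[: len(self._placed) - exclude_last]
        if len(ref) == 0:
            return np.full(len(points), np.inf)
        diff = points[:, None, :] - ref[None, :, :]
        return np.sqrt((diff * diff).sum(axis=-1)).min(axis=1)

    def _zone_ok(self, points: np.ndarray) -> np.ndarray:
        ok = np.ones(len(points), dtype=bool)
        for center, radius in self.exclusion_zones:
            ok &= np.linalg.norm(points - center[None, :], axis=1) >= radius
        return ok

    def place_first(self, d: float, clearance: float, batches: int = 30) -> np.ndarray:
        # Crowded shells fall back to a looser clearance before giving up;
        # geometry stays valid for the selection rules either way.
        for clear in (clearance, 1.3, 1.05):
            for _ in range(batches):
                points = _radial_positions(
                    _random_units(self.rng, self._BATCH), self.ligand_xyz, d
                )
                ok = np.isfinite(points).all(axis=1)
                ok &= self._min_dists_to_placed(points) >= clear
                ok &= self._zone_ok(points)
                hits = np.nonzero(ok)[0]
                if len(hits):
                    return self._accept(points[hits[0]])
        raise FixtureError(f"cannot place an atom at min-distance {d} A")

    def place_chained(
        self, d: float, previous: np.ndarray, clearance: float, batches: int = 20
    ) -> np.ndarray:
        prev_u = previous / float(np.linalg.norm(previous))
        # Angular step sized so the 3D spacing lands inside the bond window.
        base_angle = 1.45 / max(float(np.linalg.norm(previous)), 1.0)
        for clear, scale in ((clearance, 1.0), (1.3, 1.6), (1.05, 2.5)):
            width = base_angle * scale
            for _ in range(batches):
                units = prev_u[None, :] + width * self.rng.normal(
                    size=(self._BATCH, 3)
                )
                units /= np.linalg.norm(units, axis=1, keepdims=True)
                points = _radial_positions(units, self.ligand_xyz, d)
                ok = np.isfinite(points).all(axis=1)
                spacing = np.linalg.norm(points - previous[None, :], axis=1)
                ok &= (spacing >= _CHAIN_SPACING[0]) & (spacing <= _CHAIN_SPACING[1])
                ok &= self._min_dists_to_placed(points, exclude_last=1) >= clear
                ok &= self._zone_ok(points)
                hits = np.nonzero(ok)[0]
                if len(hits):
                    return self._accept(points[hits[0]])
        raise FixtureError(
            f"cannot extend the chain at min-distance {d} A (overcrowded shell?)"
        )

    def place_free(self, d: float, clearance: float, batches: int = 40) -> np.ndarray:
        for _ in range(batches):
            points = _radial_positions(
                _random_units(self.rng, self._BATCH), self.ligand_xyz, d
            )
            ok = np.isfinite(points).all(axis=1)
            ok &= self._min_dists_to_placed(points) >= clearance
            ok &= self._zone_ok(points)
            hits = np.nonzero(ok)[0]
            if len(hits):
                return self._accept(points[hits[0]])
        raise FixtureError(f"cannot place a free atom at min-distance {d} A")

    def place_near(
        self,
        anchor: np.ndarray,
        group: list[np.ndarray],
        clearance_others: float,
        batches: int = 40,
    ) -> np.ndarray:
        """A point 1.3-1.6 A from anchor, bond-scale clear of its own group,
        ``clearance_others`` clear of everything else and of the ligand."""
        group_arr = np.array(group)
        n_group_tail = 0
        # group atoms are the most recently placed ones
        for k in range(1, min(len(group), len(self._placed)) + 1):
            if any(np.allclose(self._placed[-k], g) for g in group):
                n_group_tail = k
            else:
                break
        own = group_arr[~np.all(np.isclose(group_arr, anchor), axis=1)]
        for _ in range(batches):
            radii = self.rng.uniform(1.3, 1.6, size=(self._BATCH, 1))
            points = anchor[None, :] + radii * _random_units(self.rng, self._BATCH)
            ok = self._min_dists_to_placed(points, exclude_last=n_group_tail) >= clearance_others
            if len(own):
                diff = points[:, None, :] - own[None, :, :]
                ok &= np.sqrt((diff * diff).sum(axis=-1)).min(axis=1) >= _CLEARANCE
            diff_l = points[:, None, :] - self.ligand_xyz[None, :, :]
            ok &= np.sqrt((diff_l * diff_l).sum(axis=-1)).min(axis=1) >= 1.9
            ok &= self._zone_ok(points)
            hits = np.nonzero(ok)[0]
            if len(hits):
                return self._accept(points[hits[0]])
        raise FixtureError("cannot place a chained atom near the anchor")


# ---------------------------------------------------------------------------
# Complex generation
# ---------------------------------------------------------------------------

def make_complex(spec: FixtureSpec) -> tuple[str, str, GroundTruth]:
    """Build (protein PDB text, ligand MOL2 text, ground truth).

    Shell atoms for radius r sit at exact min-distance r - 0.15 from the
    ligand, chained into 4-atom peptide-like residues (N/CA/C/O names and
    elements) with consecutive spacing below the bond-perception cutoff, so
    residues within one shell are covalently linked.  Isolated atoms and
    floating residues land inside the initial shell; waters beyond the
    largest requested radius.  The ground truth is computed by
    :func:`brute_force_pocket` on the element-guessed, altLoc-filtered
    structure (exactly what the pipeline sees).
    """
    rng = np.random.default_rng(spec.seed)
    cfg = PipelineConfig()
    ligand_xyz = _ligand_coords(spec.ligand_atom_count)
    if len(ligand_xyz) == 0:
        raise FixtureError("ligand_atom_count must be positive for a complex")
    placer = _Placer(rng, ligand_xyz)

    atoms: list[AtomRecord] = []
    bonds: set[tuple[int, int]] = set()
    serial = 0
    res_seq = 0
    chain_atoms_idx: list[int] = []  # indices into `atoms` eligible for pathologies

    def add_atom(name: str, element: str, res_name: str, chain: str,
                 rseq: int, p: np.ndarray, record: str = "ATOM") -> int:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                record_type=record,
                serial=serial,
                atom_name=name,
                res_name=res_name,
                chain_id=chain,
                res_seq=rseq,
                x=round(float(p[0]), 3),
                y=round(float(p[1]), 3),
                z=round(float(p[2]), 3),
                element=element,
            )
        )
        return serial

    # Stray isolated atoms inside the initial shell, far from everything;
    # placed first and guarded by exclusion zones so later chains cannot
    # crowd them back into connectivity.
    for _ in range(spec.n_isolated_atoms):
        res_seq += 1
        d = float(rng.uniform(2.0, min(2.8, cfg.initial_radius - 0.1)))
        p = placer.place_free(d, clearance=_ISOLATION_CLEARANCE)
        placer.exclusion_zones.append((placer.placed[-1], _ISOLATION_CLEARANCE))
        add_atom("C", "C", "UNX", "X", res_seq, p, record="HETATM")

    # Floating residues: 4-atom peptide-like units inside the initial shell,
    # clear of everything else (they survive extraction, die at the
    # connectivity filter).
    for _ in range(spec.n_disconnected_residues):
        res_seq += 1
        d = float(rng.uniform(2.0, min(2.6, cfg.initial_radius - 0.2)))
        first = placer.place_free(d, clearance=2.8)
        prev_serial = add_atom("N", "N", "GLY", "D", res_seq, first)
        group = [placer.placed[-1]]
        prev_point = group[0]
        for k in range(1, _ATOMS_PER_RESIDUE):
            name, element = _ATOM_CYCLE[k]
            p = placer.place_near(prev_point, group, clearance_others=2.8)
            group.append(placer.placed[-1])
            s = add_atom(name, element, "GLY", "D", res_seq, p)
            bonds.add((prev_serial, s))
            prev_serial, prev_point = s, placer.placed[-1]
        for q in group:
            placer.exclusion_zones.append((q, 2.8))

    radii = sorted(spec.n_shell_atoms_by_radius)
    previous_radius = 0.0
    for chain_index, radius in enumerate(radii):
        count = spec.n_shell_atoms_by_radius[radius]
        if count <= 0:
            continue
        d = radius - 0.15
        if d <= previous_radius + 0.05 or d <= 1.0:
            raise FixtureError(
                f"shell radii too close: cannot place atoms at {d:.2f} A "
                f"between radii {previous_radius} and {radius}"
            )
        chain_id = chr(ord("A") + chain_index % 20)
        prev_point: np.ndarray | None = None
        prev_serial: int | None = None
        for k in range(count):
            if k % _ATOMS_PER_RESIDUE == 0:
                res_seq += 1
            name, element = _ATOM_CYCLE[k % _ATOMS_PER_RESIDUE]
            res_name = _RES_NAMES[(res_seq - 1) % len(_RES_NAMES)]
            if prev_point is None:
                p = placer.place_first(d, _CLEARANCE)
            else:
                try:
                    p = placer.place_chained(d, prev_point, _CLEARANCE)
                except FixtureError:
                    # Dead-ended walk: restart a fresh fragment on the shell.
                    p = placer.place_first(d, _CLEARANCE)
                    prev_serial = None
            s = add_atom(name, element, res_name, chain_id, res_seq, p)
            chain_atoms_idx.append(len(atoms) - 1)
            if prev_serial is not None:
                bonds.add((prev_serial, s))
            prev_point, prev_serial = p, s
        previous_radius = radius

    # Waters beyond the largest requested shell (so controlled counts hold).
    max_radius = max(radii, default=cfg.initial_radius)
    for _ in range(spec.n_waters):
        res_seq += 1
        d = float(rng.uniform(max_radius + 0.5, max_radius + 2.0))
        p = placer.place_free(d, clearance=_CLEARANCE)
        add_atom("O", "O", "HOH", "W", res_seq, p, record="HETATM")

    # Pathology: altLoc A/B duplicate pairs on chain atoms.
    if spec.n_altloc_pairs:
        if spec.n_altloc_pairs > len(chain_atoms_idx):
            raise FixtureError("more altLoc pairs requested than chain atoms")
        chosen = sorted(
            rng.choice(len(chain_atoms_idx), size=spec.n_altloc_pairs, replace=False).tolist()
        )
        duplicates: list[tuple[int, AtomRecord]] = []
        for pick in chosen:
            idx = chain_atoms_idx[pick]
            original = atoms[idx]
            original.alt_loc = "A"
            offset = 0.3 * _random_units(rng, 1)[0]
            serial += 1
            duplicates.append(
                (
                    idx,
                    replace(
                        original,
                        serial=serial,
                        alt_loc="B",
                        x=round(original.x + float(offset[0]), 3),
                        y=round(original.y + float(offset[1]), 3),
                        z=round(original.z + float(offset[2]), 3),
                        occupancy=0.4,
                    ),
                )
            )
        for idx, dup in sorted(duplicates, key=lambda t: -t[0]):
            atoms.insert(idx + 1, dup)

    # Pathology: blank element columns (recoverable from the atom name).
    if spec.n_blank_elements:
        eligible = [a for a in atoms if a.alt_loc == " " and a.atom_name in
                    {"N", "CA", "C", "O"}]
        if spec.n_blank_elements > len(eligible):
            raise FixtureError("more blank elements requested than eligible atoms")
        for pick in rng.choice(len(eligible), size=spec.n_blank_elements,
                               replace=False).tolist():
            eligible[pick].element = ""

    protein = Structure(atoms=atoms, bonds=bonds)
    pdb_text = write_pdb(protein)
    mol2_text = make_ligand_mol2(spec.ligand_atom_count, name=spec.ligand_name)

    processed = filter_altloc(guess_elements(parse_pdb(pdb_text)), cfg.keep_altloc)
    ligand = parse_mol2(mol2_text)
    truth = _ground_truth(processed, ligand, cfg, radii)
    return pdb_text, mol2_text, truth


def _ground_truth(
    protein: Structure, ligand: LigandSpec, cfg: PipelineConfig, radii: list[float]
) -> GroundTruth:
    pocket, final_radius, iterations, exhausted = brute_force_pocket(
        protein, ligand, cfg
    )
    shells = {
        r: tuple(a.serial for a in _shell_loop(protein, ligand, r)) for r in radii
    }
    return GroundTruth(
        pocket_serials=tuple(a.serial for a in pocket),
        final_radius=final_radius,
        iterations_used=iterations,
        expansion_exhausted=exhausted,
        n_protein_atoms=len(protein.atoms),
        shell_serials_by_radius=shells,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle (explicit loops only; used in tests and ground truth)
# ---------------------------------------------------------------------------

def _dist(a: AtomRecord, b: AtomRecord) -> float:
    dx = a.x - b.x
    dy = a.y - b.y
    dz = a.z - b.z
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def _min_dist_to_ligand_loop(atom: AtomRecord, ligand: LigandSpec) -> float:
    best = math.inf
    for la in ligand.structure.atoms:
        d = _dist(atom, la)
        if d < best:
            best = d
    return best


def _shell_loop(protein: Structure, ligand: LigandSpec, radius: float) -> list[AtomRecord]:
    out = []
    for atom in protein.atoms:
        if _min_dist_to_ligand_loop(atom, ligand) <= radius:
            out.append(atom)
    return out


def brute_force_pocket(
    protein: Structure, ligand: LigandSpec, cfg: PipelineConfig | None = None
) -> tuple[list[AtomRecord], float, int, bool]:
    """Naive re-implementation of the extraction rules (the test oracle).

    Returns ``(atoms, final_radius, iterations_used, exhausted)``.
    """
    cfg = cfg or PipelineConfig()
    n_lig = len(ligand.structure.atoms)
    if n_lig == 0:
        raise LigandSizeError("ligand not present (zero atoms)")
    if n_lig > cfg.max_ligand_atoms:
        raise LigandSizeError(f"ligand has {n_lig} atoms (> {cfg.max_ligand_atoms})")

    # Iterative shell expansion.
    shell: list[AtomRecord] = []
    radius = cfg.initial_radius
    iterations = 0
    exhausted = True
    for iteration in range(cfg.max_expansion_attempts + 1):
        radius = cfg.initial_radius + cfg.radius_step * iteration
        shell = _shell_loop(protein, ligand, radius)
        iterations = iteration
        if len(shell) >= cfg.min_pocket_atoms:
            exhausted = False
            break

    # Residue completion.
    wanted = set()
    for atom in shell:
        wanted.add(atom.residue_id)
    preliminary = [a for a in protein.atoms if a.residue_id in wanted]

    # Cap extension (atom-level, excluding ligand and water).
    extended_serials = {a.serial for a in preliminary}
    if preliminary:
        for atom in protein.atoms:
            if atom.serial in extended_serials:
                continue
            if atom.res_name in cfg.water_res_names or atom.res_name == ligand.name:
                continue
            for patom in preliminary:
                if _dist(atom, patom) <= cfg.cap_extension_radius:
                    extended_serials.add(atom.serial)
                    break
    extended = [a for a in protein.atoms if a.serial in extended_serials]

    # Isolated-atom cleanup: single pass over the extended set.
    final = []
    for atom in extended:
        has_neighbor = False
        for other in extended:
            if other.serial == atom.serial:
                continue
            if _dist(atom, other) <= cfg.isolation_cutoff:
                has_neighbor = True
                break
        if has_neighbor:
            final.append(atom)
    return final, radius, iterations, exhausted


def random_fixture_spec(seed: int) -> FixtureSpec:
    """A randomized-but-feasible FixtureSpec for property testing."""
    rng = np.random.default_rng(seed)
    ligand_atoms = int(rng.integers(8, 21))
    n_isolated = int(rng.integers(0, 3))
    n_disconnected = int(rng.integers(0, 2))
    # Keep dense shells feasible: stray atoms carve out exclusion zones, so
    # cap the initial-shell occupancy accordingly.
    max_initial = 78 - 8 * n_isolated - 10 * n_disconnected
    shells: dict[float, int] = {3.0: int(rng.integers(25, max_initial))}
    if rng.random() < 0.5:
        shells[3.5] = int(rng.integers(4, 30))
    if rng.random() < 0.3:
        shells[4.5] = int(rng.integers(4, 20))
    return FixtureSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_shell_atoms_by_radius=shells,
        ligand_atom_count=ligand_atoms,
        n_altloc_pairs=int(rng.integers(0, 4)),
        n_isolated_atoms=n_isolated,
        n_waters=int(rng.integers(0, 4)),
        n_disconnected_residues=n_disconnected,
        n_blank_elements=int(rng.integers(0, 6)),
    )
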