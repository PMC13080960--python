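"""Shared builders for the test suite (everything generated in memory)."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pocketprep.structure_io import AtomRecord, LigandSpec, Structure


def atom(
    serial: int,
    x: float,
    y: float,
    z: float,
    name: str = "C",
    element: str = "C",
    res_name: str = "ALA",
    res_seq: int = 1,
    chain: str = "A",
    record: str = "ATOM",
    alt_loc: str = " ",
    icode: str = " ",
) -> AtomRecord:
    return AtomRecord(
        record_type=record,
        serial=serial,
        atom_name=name,
        alt_loc=alt_loc,
        res_name=res_name,
        chain_id=chain,
        res_seq=res_seq,
        insertion_code=icode,
        x=x,
        y=y,
        z=z,
        element=element,
    )


def sphere_points(n: int, radius: float) -> np.ndarray:
    """n deterministic points on a sphere (golden-spiral layout)."""
    pts = np.zeros((n, 3))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i in range(n):
        z = 1.0 - (2.0 * i + 1.0) / n
        r = math.sqrt(max(1.0 - z * z, 0.0))
        theta = golden * i
        pts[i] = (r * math.cos(theta), r * math.sin(theta), z)
    return pts * radius


def shell_protein(counts_by_radius: dict[float, int], res_size: int = 4) -> Structure:
    """Protein with exactly ``counts_by_radius[r]`` atoms at distance r from
    the origin, grouped into residues of ``res_size`` atoms."""
    atoms = []
    serial = 0
    res_seq = 0
    for radius in sorted(counts_by_radius):
        for i, p in enumerate(sphere_points(counts_by_radius[radius], radius)):
            if serial % res_size == 0:
                res_seq += 1
            serial += 1
            atoms.append(atom(serial, *p, res_seq=res_seq))
    return Structure(atoms=atoms)


def point_ligand(name: str = "LIG") -> LigandSpec:
    """Single carbon at the origin."""
    structure = Structure(
        atoms=[atom(1, 0.0, 0.0, 0.0, name="C1", res_name=name, record="HETATM")]
    )
    return LigandSpec(name=name, structure=structure)


# Glycine dipeptide heavy-atom skeleton with realistic bond geometry
# (peptide C-N 1.33 A); OXT extends residue 2 into a carboxylate.
GLY_DIPEPTIDE_COORDS = {
    ("N", 1): (-0.525, 1.363, 0.000),
    ("CA", 1): (0.000, 0.000, 0.000),
    ("C", 1): (1.526, 0.000, 0.000),
    ("O", 1): (2.153, -0.774, -0.714),
    ("N", 2): (2.250, 0.844, 0.730),
    ("CA", 2): (3.700, 0.844, 0.730),
    ("C", 2): (4.226, 2.204, 1.050),
    ("O", 2): (5.326, 2.704, 0.750),
}
GLY_OXT = (3.461, 2.943, 1.709)


@pytest.fixture
def dipeptide() -> Structure:
    atoms = []
    for serial, ((name, res_seq), xyz) in enumerate(
        GLY_DIPEPTIDE_COORDS.items(), start=1
    ):
        atoms.append(
            atom(serial, *xyz, name=name, element=name[0], res_name="GLY",
                 res_seq=res_seq)
        )
    return Structure(atoms=atoms)


@pytest.fixture
def dipeptide_with_oxt(dipeptide: Structure) -> Structure:
    s = dipeptide.copy()
    s.atoms.append(
        atom(len(s.atoms) + 1, *GLY_OXT, name="OXT", element="O", res_name="GLY",
             res_seq=2)
    )
    return s
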