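"""Constraint generation and command assembly for the external
conformer-rotamer sampler (CREST).

The merged PDB's atom order is the single source of truth for 1-based
constraint indices.  Constraint files use xcontrol syntax and are written
natively when the binary is absent; the range separator is an ASCII hyphen.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .config import PipelineConfig
from .errors import ConstraintError, CrestError
from .structure_io import Structure

__all__ = [
    "ConstraintSpec",
    "constrained_atom_indices",
    "compress_ranges",
    "expand_ranges",
    "make_constraint_spec",
    "write_constraints",
    "parse_constraints",
    "build_crest_command",
    "run_crest",
    "SubprocessCrestRunner",
    "MockCrestRunner",
    "CONSTRAINTS_FILE_NAME",
    "CONFORMERS_XYZ_NAME",
    "CREST_LOG_NAME",
]

CONSTRAINTS_FILE_NAME = "constraints.inp"
CONFORMERS_XYZ_NAME = "crest_conformers.xyz"
CREST_LOG_NAME = "crest.out"
DEFAULT_FORCE_CONSTANT = "0.5"

# runner(command, outdir) -> (returncode, combined stdout/stderr text)
Runner = Callable[[Sequence[str], Path], tuple[int, str]]


@dataclass
class ConstraintSpec:
    """1-based constrained-atom index set plus its compressed range text."""

    constrained_indices: tuple[int, ...]
    free_indices: tuple[int, ...]
    range_text: str
    reference_pdb: str
    force_field_level: str = "gfnff"
    temperature: str = "310"
    extra_args: str = "-squick"


def constrained_atom_indices(merged: Structure, ligand_name: str) -> list[int]:
    """1-based positions (file order) of every atom not in the ligand residue."""
    if not any(a.res_name == ligand_name for a in merged.atoms):
        raise ConstraintError(
            f"ligand residue {ligand_name!r} absent from the merged structure; "
            "constraining every atom would freeze the ligand"
        )
    return [i for i, a in enumerate(merged.atoms, start=1) if a.res_name != ligand_name]


def compress_ranges(indices: Sequence[int]) -> str:
    """Render maximal runs of consecutive integers as 'a-b' (singletons 'a'),
    comma-joined.  Input must be strictly increasing positive integers."""
    for k, value in enumerate(indices):
        if value < 1:
            raise ConstraintError(f"index {value} is not a positive integer")
        if k and value <= indices[k - 1]:
            raise ConstraintError("indices must be strictly increasing")
    parts: list[str] = []
    k = 0
    n = len(indices)
    while k < n:
        start = indices[k]
        while k + 1 < n and indices[k + 1] == indices[k] + 1:
            k += 1
        end = indices[k]
        parts.append(str(start) if start == end else f"{start}-{end}")
        k += 1
    return ",".join(parts)


def expand_ranges(text: str) -> list[int]:
    """Inverse of :func:`compress_ranges`."""
    out: list[int] = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(part))
    return out


def make_constraint_spec(
    merged: Structure,
    ligand_name: str,
    reference_pdb: str,
    cfg: PipelineConfig | None = None,
) -> ConstraintSpec:
    cfg = cfg or PipelineConfig()
    constrained = constrained_atom_indices(merged, ligand_name)
    all_positions = set(range(1, len(merged.atoms) + 1))
    free = sorted(all_positions - set(constrained))
    return ConstraintSpec(
        constrained_indices=tuple(constrained),
        free_indices=tuple(free),
        range_text=compress_ranges(constrained),
        reference_pdb=reference_pdb,
        force_field_level=cfg.crest_level,
        temperature=cfg.crest_temp,
        extra_args=cfg.crest_extra,
    )


def write_constraints(
    spec: ConstraintSpec,
    outdir: str | Path,
    force_constant: str = DEFAULT_FORCE_CONSTANT,
) -> Path:
    """Write ``constraints.inp`` in xcontrol syntax.

    Mirrors the sample file the external generator produces (atoms line,
    force constant, reference clause, metadynamics-active complement).
    """
    if not spec.constrained_indices:
        raise ConstraintError("empty constrained set: nothing to constrain")
    outdir = Path(outdir)
    lines = [
        "$constrain",
        f"  atoms: {spec.range_text}",
        f"  force constant={force_constant}",
        f"  reference={spec.reference_pdb}",
    ]
    if spec.free_indices:
        lines += ["$metadyn", f"  atoms: {compress_ranges(list(spec.free_indices))}"]
    lines.append("$end")
    path = outdir / CONSTRAINTS_FILE_NAME
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_constraints(text: str) -> list[int]:
    """Recover the constrained indices from an xcontrol constraint file."""
    in_constrain = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("$"):
            in_constrain = stripped == "$constrain"
            continue
        if in_constrain and stripped.lower().startswith("atoms:"):
            return expand_ranges(stripped.split(":", 1)[1])
    raise ConstraintError("no '$constrain/atoms:' entry found")


def build_crest_command(
    final_pdb: str | Path,
    spec: ConstraintSpec,
    constraints_file: str = CONSTRAINTS_FILE_NAME,
    executable: str = "crest",
) -> list[str]:
    """Assemble the sampler argument vector (pure; extra args are
    whitespace-tokenized, never shell-interpreted)."""
    level = spec.force_field_level
    level_flag = level if level.startswith("-") else f"--{level}"
    cmd = [
        executable,
        str(final_pdb),
        "--cinp",
        constraints_file,
        "--temp",
        spec.temperature,
        level_flag,
    ]
    cmd.extend(spec.extra_args.split())
    return cmd


class SubprocessCrestRunner:
    """Real runner: executes the sampler binary inside ``outdir``."""

    def __call__(self, command: Sequence[str], outdir: Path) -> tuple[int, str]:
        if shutil.which(command[0]) is None:
            raise CrestError(
                f"{command[0]!r} not found on PATH; install it or rerun with "
                "--no-crest to stop after constraint generation"
            )
        proc = subprocess.run(
            list(command),
            cwd=outdir,
            stdout=subprocess.PIPE,
            stderr=subprocess.STDOUT,
            text=True,
        )
        return proc.returncode, proc.stdout


@dataclass
class MockCrestRunner:
    """Deterministic stand-in for the sampler used in tests.

    Reads the input structure named in the command, emits ``n_frames``
    jittered copies of its coordinates as a multi-frame XYZ (with energy
    comment lines) plus a canned log.  Same seed -> byte-identical output.
    """

    n_frames: int = 3
    seed: int = 0
    jitter: float = 0.05
    returncode: int = 0

    def __call__(self, command: Sequence[str], outdir: Path) -> tuple[int, str]:
        import numpy as np

        from .structure_io import parse_pdb

        if self.returncode != 0:
            log = "mock crest: simulated failure\n" + "error: something went wrong\n"
            return self.returncode, log
        structure_path = Path(command[1])
        if not structure_path.is_absolute():
            structure_path = Path(outdir) / structure_path
        structure = parse_pdb(structure_path.read_text())
        rng = np.random.default_rng(self.seed)
        xyz = structure.coords_array()
        lines: list[str] = []
        for frame in range(self.n_frames):
            coords = xyz + rng.normal(0.0, self.jitter, xyz.shape)
            energy = -10.0 - 0.01 * frame
            lines.append(str(len(structure.atoms)))
            lines.append(f" {energy:.8f}")
            for atom, (x, y, z) in zip(structure.atoms, coords):
                lines.append(f"{atom.element or 'X':<2} {x:18.10f} {y:18.10f} {z:18.10f}")
        (Path(outdir) / CONFORMERS_XYZ_NAME).write_text("\n".join(lines) + "\n")
        log = (
            "mock crest run\n"
            f"command: {' '.join(command)}\n"
            f"{self.n_frames} conformers written\n"
            "CREST terminated normally.\n"
        )
        return 0, log


def run_crest(
    command: Sequence[str],
    outdir: str | Path,
    runner: Runner | None = None,
) -> tuple[Path, Path]:
    """Execute the sampler; capture the log to ``crest.out``.

    Returns ``(conformers_xyz_path, log_path)``.  A nonzero exit raises
    :class:`CrestError` carrying the tail of the log.
    """
    outdir = Path(outdir)
    runner = runner or SubprocessCrestRunner()
    returncode, output = runner(command, outdir)
    log_path = outdir / CREST_LOG_NAME
    log_path.write_text(output)
    if returncode != 0:
        tail = "\n".join(output.splitlines()[-20:])
        raise CrestError(
            f"sampler exited with code {returncode}; log tail:\n{tail}"
        )
    xyz_path = outdir / CONFORMERS_XYZ_NAME
    if not xyz_path.exists():
        raise CrestError(f"sampler produced no {CONFORMERS_XYZ_NAME} in {outdir}")
    return xyz_path, log_path
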