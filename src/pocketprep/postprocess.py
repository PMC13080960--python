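"""Conformer-ensemble postprocessing: split multi-model PDBs, transfer
template atom/residue metadata onto each frame, write the annotated
multi-PDB, and delete temporary files.

The external XYZ-to-PDB conversion step is replaced by a native positional
mapping against the template; element symbols are cross-checked per position
to guard against reordered sampler output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EnsembleError
from .structure_io import AtomRecord, Structure, parse_pdb, write_pdb
from .elements import canonical_symbol

__all__ = [
    "AtomMeta",
    "ConformerEnsemble",
    "split_models",
    "extract_template_metadata",
    "apply_metadata",
    "xyz_to_conformers",
    "xyz_to_plain_pdb",
    "write_updated_ensemble",
    "cleanup_temp_files",
    "UPDATED_CONFORMERS_NAME",
    "PLAIN_CONFORMERS_NAME",
    "TEMP_FILE_NAMES",
    "PROTECTED_FILE_NAMES",
]

UPDATED_CONFORMERS_NAME = "crest_conformers_updated.pdb"
PLAIN_CONFORMERS_NAME = "crest_conformers.pdb"

# Intermediates eligible for deletion, and outputs that must always survive.
TEMP_FILE_NAMES: tuple[str, ...] = (
    "pre_prepared.pdb",
    "prepared.pdb",
    "pocket_connected.pdb",
    "pocket_protonated.pdb",
    ".xcontrol.sample",
)
PROTECTED_FILE_NAMES: tuple[str, ...] = (
    UPDATED_CONFORMERS_NAME,
    PLAIN_CONFORMERS_NAME,
    "crest_conformers.xyz",
    "crest.out",
)


@dataclass(frozen=True)
class AtomMeta:
    """Per-atom template metadata transferred onto each conformer."""

    atom_name: str
    res_name: str
    res_seq: int
    chain_id: str
    element: str
    record_type: str = "ATOM"
    insertion_code: str = " "
    name_raw: str = ""


@dataclass
class ConformerEnsemble:
    """Ordered coordinate frames sharing one atom-metadata template."""

    frames: list[np.ndarray]
    template: list[AtomMeta]
    titles: list[str]

    def __post_init__(self) -> None:
        n = len(self.template)
        for k, frame in enumerate(self.frames):
            if frame.shape != (n, 3):
                raise EnsembleError(
                    f"frame {k} has shape {frame.shape}, expected ({n}, 3)"
                )
            if not np.all(np.isfinite(frame)):
                raise EnsembleError(f"frame {k} contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)


def split_models(multi_pdb_text: str) -> list[str]:
    """Split a multi-model PDB on MODEL/ENDMDL into per-conformer texts.

    A model-less file is returned as a single conformer.  Both the standard
    ENDMDL keyword and the spelled-out ENDMODEL variant close a block;
    unbalanced records raise an error naming the line.
    """
    models: list[list[str]] = []
    current: list[str] | None = None
    open_line = 0
    saw_model = False
    for lineno, line in enumerate(multi_pdb_text.splitlines(), start=1):
        keyword = line.split()[0] if line.split() else ""
        if keyword == "MODEL":
            if current is not None:
                raise EnsembleError(
                    f"line {lineno}: MODEL opened before ENDMDL of line {open_line}"
                )
            current = []
            open_line = lineno
            saw_model = True
        elif keyword in ("ENDMDL", "ENDMODEL"):
            if current is None:
                raise EnsembleError(f"line {lineno}: {keyword} without MODEL")
            models.append(current)
            current = None
        elif current is not None:
            current.append(line)
    if current is not None:
        raise EnsembleError(f"MODEL opened at line {open_line} is never closed")
    if not saw_model:
        return [multi_pdb_text]
    return ["\n".join(m) + "\n" for m in models]


def extract_template_metadata(template: str | Structure) -> list[AtomMeta]:
    """Ordered (name, residue, chain, element) records per template atom."""
    structure = parse_pdb(template) if isinstance(template, str) else template
    return [
        AtomMeta(
            atom_name=a.atom_name,
            res_name=a.res_name,
            res_seq=a.res_seq,
            chain_id=a.chain_id,
            element=a.element,
            record_type=a.record_type,
            insertion_code=a.insertion_code,
            name_raw=a.name_raw,
        )
        for a in structure.atoms
    ]


def apply_metadata(conformer: Structure, metadata: Sequence[AtomMeta]) -> Structure:
    """Overwrite naming fields by position; coordinates stay untouched."""
    if len(conformer.atoms) != len(metadata):
        raise EnsembleError(
            f"conformer has {len(conformer.atoms)} atoms but the template has "
            f"{len(metadata)}; atom order cannot be trusted"
        )
    atoms = [
        replace(
            atom,
            atom_name=meta.atom_name,
            res_name=meta.res_name,
            res_seq=meta.res_seq,
            chain_id=meta.chain_id,
            element=meta.element,
            record_type=meta.record_type,
            insertion_code=meta.insertion_code,
            name_raw=meta.name_raw,
        )
        for atom, meta in zip(conformer.atoms, metadata)
    ]
    return Structure(atoms=atoms, bonds=set(conformer.bonds), title=conformer.title)


def _parse_xyz_frames(xyz_text: str) -> list[tuple[str, list[str], np.ndarray]]:
    lines = xyz_text.splitlines()
    frames: list[tuple[str, list[str], np.ndarray]] = []
    pos = 0
    index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise EnsembleError(
                f"frame {index}: malformed atom-count header {lines[pos]!r}"
            ) from exc
        title = lines[pos + 1] if pos + 1 < len(lines) else ""
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise EnsembleError(f"frame {index}: truncated ({len(body)}/{natoms} atoms)")
        symbols: list[str] = []
        coords = np.zeros((natoms, 3))
        for k, line in enumerate(body):
            tokens = line.split()
            if len(tokens) < 4:
                raise EnsembleError(f"frame {index}: short atom line {line!r}")
            symbols.append(tokens[0])
            coords[k] = [float(t) for t in tokens[1:4]]
        frames.append((title.strip(), symbols, coords))
        pos += 2 + natoms
        index += 1
    return frames


def xyz_to_conformers(xyz_text: str, metadata: Sequence[AtomMeta]) -> ConformerEnsemble:
    """Map multi-frame XYZ onto the template; element mismatch is an error.

    Energy/comment lines are not interpreted but preserved as frame titles.
    """
    parsed = _parse_xyz_frames(xyz_text)
    if not parsed:
        raise EnsembleError("XYZ text contains no frames")
    frames: list[np.ndarray] = []
    titles: list[str] = []
    for index, (title, symbols, coords) in enumerate(parsed):
        if len(symbols) != len(metadata):
            raise EnsembleError(
                f"frame {index} has {len(symbols)} atoms, template has {len(metadata)}"
            )
        for position, (symbol, meta) in enumerate(zip(symbols, metadata), start=1):
            if meta.element and canonical_symbol(symbol) != meta.element:
                raise EnsembleError(
                    f"frame {index}: element mismatch at position {position} "
                    f"({symbol!r} vs template {meta.element!r})"
                )
        frames.append(coords)
        titles.append(title)
    return ConformerEnsemble(frames=frames, template=list(metadata), titles=titles)


def _meta_to_atom(meta: AtomMeta, serial: int, xyz: np.ndarray) -> AtomRecord:
    return AtomRecord(
        record_type=meta.record_type,
        serial=serial,
        atom_name=meta.atom_name,
        res_name=meta.res_name,
        chain_id=meta.chain_id,
        res_seq=meta.res_seq,
        insertion_code=meta.insertion_code,
        x=float(xyz[0]),
        y=float(xyz[1]),
        z=float(xyz[2]),
        element=meta.element,
        name_raw=meta.name_raw,
    )


def write_updated_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> str:
    """Write a MODEL/ENDMDL-delimited multi-PDB of the annotated frames."""
    if len(ensemble) == 0:
        raise EnsembleError("refusing to write an empty ensemble")
    chunks: list[str] = []
    for k, (frame, title) in enumerate(zip(ensemble.frames, ensemble.titles), start=1):
        chunks.append(f"MODEL     {k:>4}")
        if title:
            chunks.append(f"REMARK 250 {title}")
        structure = Structure(
            atoms=[
                _meta_to_atom(meta, serial, xyz)
                for serial, (meta, xyz) in enumerate(zip(ensemble.template, frame), start=1)
            ]
        )
        body = write_pdb(structure)
        chunks.extend(line for line in body.splitlines() if line != "END")
        chunks.append("ENDMDL")
    chunks.append("END")
    text = "\n".join(chunks) + "\n"
    Path(path).write_text(text)
    return text


def xyz_to_plain_pdb(xyz_text: str, path: str | Path | None = None) -> str:
    """Generic XYZ-to-multi-PDB conversion without template annotation
    (element-derived atom names, UNL residue), mirroring what a plain format
    converter would emit."""
    parsed = _parse_xyz_frames(xyz_text)
    if not parsed:
        raise EnsembleError("XYZ text contains no frames")
    chunks: list[str] = []
    for k, (title, symbols, coords) in enumerate(parsed, start=1):
        chunks.append(f"MODEL     {k:>4}")
        if title:
            chunks.append(f"REMARK 250 {title}")
        atoms = [
            AtomRecord(
                record_type="HETATM",
                serial=serial,
                atom_name=f"{canonical_symbol(sym) or sym}{serial}"[:4],
                res_name="UNL",
                res_seq=1,
                x=float(xyz[0]),
                y=float(xyz[1]),
                z=float(xyz[2]),
                element=canonical_symbol(sym) or "",
            )
            for serial, (sym, xyz) in enumerate(zip(symbols, coords), start=1)
        ]
        body = write_pdb(Structure(atoms=atoms))
        chunks.extend(line for line in body.splitlines() if line != "END")
        chunks.append("ENDMDL")
    chunks.append("END")
    text = "\n".join(chunks) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def cleanup_temp_files(outdir: str | Path, keep: set[str] | None = None) -> list[str]:
    """Delete known intermediates from ``outdir``; returns removed names.

    Final outputs (conformer files, sampler log) and anything in ``keep``
    always survive; missing files are skipped silently.
    """
    outdir = Path(outdir)
    keep = set(keep or ())
    removed: list[str] = []
    for name in TEMP_FILE_NAMES:
        if name in keep or name in PROTECTED_FILE_NAMES:
            continue
        target = outdir / name
        if target.exists():
            target.unlink()
            removed.append(name)
    return removed
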