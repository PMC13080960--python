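"""End-to-end orchestration and the command-line interface.

Seven stages: setup/parsing, input preprocessing, pocket extraction,
hydrogenation, merging + charge computation, constrained conformer search
(optional), cleanup/reporting.  Each run works inside a dedicated output
subdirectory and records every produced file and warning in a
machine-readable manifest.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
import logging
import shutil
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import crest as crest_mod
from . import postprocess as post_mod
from .cleanup import (
    OpenBabelBackend,
    ProtonationBackend,
    SimpleGeometricBackend,
    StubProtonationBackend,
    compute_formal_charge,
    filter_connected_residues,
    merge,
    perceive_bonds,
    protonate,
    strip_hydrogens,
)
from .config import PipelineConfig
from .errors import PipelineError, PocketPrepError
from .pocket import POCKET_FILE_NAME, extract_pocket
from .structure_io import (
    Structure,
    filter_altloc,
    guess_elements,
    parse_mol2,
    parse_pdb,
    write_pdb,
)

__all__ = ["RunManifest", "parse_args", "run_pipeline", "main", "STAGE_EXIT_CODES"]

logger = logging.getLogger("pocketprep")

PRE_PREPARED_NAME = "pre_prepared.pdb"
PREPARED_NAME = "prepared.pdb"
CONNECTED_NAME = "pocket_connected.pdb"
PROTONATED_NAME = "pocket_protonated.pdb"
FINAL_PDB_NAME = "final_structure.pdb"
MANIFEST_NAME = "run_manifest.json"

STAGE_EXIT_CODES = {
    "setup": 2,
    "preprocess": 3,
    "pocket": 4,
    "hydrogenation": 5,
    "merge": 6,
    "crest": 7,
    "postprocess": 8,
    "cleanup": 9,
}


@dataclass
class RunManifest:
    """What a run consumed, produced, and warned about."""

    protein_file: str
    ligand_file: str
    outdir: str
    no_crest: bool = False
    config: PipelineConfig = field(default_factory=PipelineConfig)
    ligand_name: str = ""
    formal_charge: int | None = None
    pocket_atom_count: int | None = None
    final_radius: float | None = None
    iterations_used: int | None = None
    produced_files: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["config"]["water_res_names"] = sorted(
            self.config.water_res_names
        )
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def parse_args(argv: list[str] | None = None) -> RunManifest:
    """Parse CLI arguments into a RunManifest skeleton."""
    parser = argparse.ArgumentParser(
        prog="pocketprep",
        description=(
            "Carve a binding pocket around a posed ligand, clean and "
            "protonate it, and prepare constrained conformer-sampling inputs."
        ),
    )
    parser.add_argument("protein_file", help="protein structure (PDB)")
    parser.add_argument("ligand_file", help="posed ligand (TRIPOS MOL2, 3D)")
    parser.add_argument(
        "outdir", help="name of the output subdirectory (created if missing)"
    )
    parser.add_argument(
        "--no-crest",
        action="store_true",
        help="skip the conformer search; stop after writing constraints.inp",
    )
    parser.add_argument("--temp", default="310", help="sampler temperature (default 310)")
    parser.add_argument(
        "--lvl-of-theory",
        default="gfnff",
        help="sampler level of theory flag (default gfnff)",
    )
    parser.add_argument(
        "--extra-crest-arguments",
        default="-squick",
        help="extra sampler arguments, whitespace-tokenized (default '-squick')",
    )
    parser.add_argument(
        "--keep-altloc", default="A", help="alternate location indicator to keep"
    )
    parser.add_argument(
        "--protonation",
        choices=("auto", "openbabel", "simple", "none"),
        default="auto",
        help="protonation backend (auto: Open Babel if installed, else the "
        "built-in valence filler)",
    )
    args = parser.parse_args(argv)
    config = PipelineConfig(
        crest_temp=args.temp,
        crest_level=args.lvl_of_theory,
        crest_extra=args.extra_crest_arguments,
        keep_altloc=args.keep_altloc,
    )
    manifest = RunManifest(
        protein_file=args.protein_file,
        ligand_file=args.ligand_file,
        outdir=args.outdir,
        no_crest=args.no_crest,
        config=config,
    )
    manifest.protonation_choice = args.protonation  # type: ignore[attr-defined]
    return manifest


def _resolve_backend(choice: str) -> ProtonationBackend | None:
    if choice == "openbabel":
        return OpenBabelBackend()
    if choice == "simple":
        return SimpleGeometricBackend()
    if choice == "none":
        return None
    # auto
    if shutil.which("obabel"):
        return OpenBabelBackend()
    logger.info("obabel not found; using the built-in valence-filling backend")
    return SimpleGeometricBackend()


def run_pipeline(
    manifest: RunManifest,
    runner: crest_mod.Runner | None = None,
    protonation_backend: ProtonationBackend | None = None,
    base_dir: str | Path | None = None,
) -> RunManifest:
    """Execute the pipeline; returns the completed manifest.

    ``runner`` overrides the sampler invocation (tests use a mock);
    ``protonation_backend`` overrides backend discovery.  All outputs land
    inside ``base_dir/outdir`` (``base_dir`` defaults to the current
    directory); nothing is written outside it.
    """
    cfg = manifest.config
    base = Path(base_dir) if base_dir is not None else Path.cwd()
    outdir = base / manifest.outdir
    stage = "setup"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            protein_path = Path(manifest.protein_file)
            ligand_path = Path(manifest.ligand_file)
            if not protein_path.is_file():
                raise PipelineError(stage, f"protein file not readable: {protein_path}")
            if not ligand_path.is_file():
                raise PipelineError(stage, f"ligand file not readable: {ligand_path}")
            outdir.mkdir(parents=True, exist_ok=True)

            def produced(name: str, path: Path) -> None:
                manifest.produced_files[name] = str(path)

            # Stage 2: input preprocessing.
            stage = "preprocess"
            raw = parse_pdb(protein_path.read_text())
            fixed = guess_elements(raw)
            write_pdb(fixed, outdir / PRE_PREPARED_NAME)
            produced(PRE_PREPARED_NAME, outdir / PRE_PREPARED_NAME)
            prepared = filter_altloc(fixed, cfg.keep_altloc)
            write_pdb(prepared, outdir / PREPARED_NAME)
            produced(PREPARED_NAME, outdir / PREPARED_NAME)
            ligand = parse_mol2(ligand_path.read_text())
            manifest.ligand_name = ligand.name
            logger.info("ligand %r: %d atoms", ligand.name, len(ligand.structure.atoms))

            # Stage 3: pocket extraction.
            stage = "pocket"
            selection = extract_pocket(
                prepared, ligand, cfg, out_path=outdir / POCKET_FILE_NAME
            )
            produced(POCKET_FILE_NAME, outdir / POCKET_FILE_NAME)
            manifest.pocket_atom_count = len(selection)
            manifest.final_radius = selection.final_radius
            manifest.iterations_used = selection.iterations_used
            logger.info(
                "pocket: %d atoms, radius %.1f A after %d expansion(s)",
                len(selection),
                selection.final_radius,
                selection.iterations_used,
            )
            if len(selection) == 0:
                raise PipelineError(stage, "pocket extraction selected no atoms")
            pocket_structure = prepared.subset(selection.serials)

            # Stage 4: hydrogenation (dehydrogenate -> bonds -> filter -> protonate).
            stage = "hydrogenation"
            heavy = strip_hydrogens(pocket_structure)
            bonded = perceive_bonds(heavy)
            connected = filter_connected_residues(bonded)
            logger.info(
                "connectivity filter: %d -> %d atoms", len(bonded), len(connected)
            )
            write_pdb(connected, outdir / CONNECTED_NAME)
            produced(CONNECTED_NAME, outdir / CONNECTED_NAME)
            if len(connected) == 0:
                raise PipelineError(
                    stage, "no residue has a covalent link to another residue"
                )
            backend = protonation_backend
            if backend is None:
                backend = _resolve_backend(
                    getattr(manifest, "protonation_choice", "auto")
                )
            if backend is not None:
                protonated = protonate(connected, cfg.protonation_pH, backend)
            else:
                protonated = connected
            write_pdb(protonated, outdir / PROTONATED_NAME)
            produced(PROTONATED_NAME, outdir / PROTONATED_NAME)

            # Stage 5: merge and formal charge.
            stage = "merge"
            merged = merge(protonated, ligand)
            write_pdb(merged, outdir / FINAL_PDB_NAME)
            produced(FINAL_PDB_NAME, outdir / FINAL_PDB_NAME)
            charge = compute_formal_charge(merged)
            manifest.formal_charge = charge.total_formal_charge
            logger.info("total formal charge: %+d", charge.total_formal_charge)

            # Stage 6: constrained conformer search (constraints always written).
            stage = "crest"
            lig_res_name = next(
                a.res_name for a in reversed(merged.atoms)
            )  # ligand atoms are last
            spec = crest_mod.make_constraint_spec(
                merged, lig_res_name, FINAL_PDB_NAME, cfg
            )
            crest_mod.write_constraints(spec, outdir)
            produced(
                crest_mod.CONSTRAINTS_FILE_NAME,
                outdir / crest_mod.CONSTRAINTS_FILE_NAME,
            )
            if not manifest.no_crest:
                command = crest_mod.build_crest_command(FINAL_PDB_NAME, spec)
                xyz_path, log_path = crest_mod.run_crest(command, outdir, runner)
                produced(crest_mod.CONFORMERS_XYZ_NAME, xyz_path)
                produced(crest_mod.CREST_LOG_NAME, log_path)

                # Stage 7a: conformer re-annotation.
                stage = "postprocess"
                metadata = post_mod.extract_template_metadata(
                    (outdir / FINAL_PDB_NAME).read_text()
                )
                xyz_text = xyz_path.read_text()
                post_mod.xyz_to_plain_pdb(
                    xyz_text, outdir / post_mod.PLAIN_CONFORMERS_NAME
                )
                produced(
                    post_mod.PLAIN_CONFORMERS_NAME,
                    outdir / post_mod.PLAIN_CONFORMERS_NAME,
                )
                ensemble = post_mod.xyz_to_conformers(xyz_text, metadata)
                post_mod.write_updated_ensemble(
                    ensemble, outdir / post_mod.UPDATED_CONFORMERS_NAME
                )
                produced(
                    post_mod.UPDATED_CONFORMERS_NAME,
                    outdir / post_mod.UPDATED_CONFORMERS_NAME,
                )
                logger.info("annotated %d conformer(s)", len(ensemble))

            # Stage 7b: temp-file cleanup + manifest.
            stage = "cleanup"
            removed = post_mod.cleanup_temp_files(outdir)
            for name in removed:
                manifest.produced_files.pop(name, None)
            logger.info("removed temporaries: %s", ", ".join(removed) or "none")
        except PipelineError:
            raise
        except PocketPrepError as exc:
            raise PipelineError(stage, str(exc)) from exc
        finally:
            manifest.warnings.extend(str(w.message) for w in caught)

    manifest.produced_files[MANIFEST_NAME] = str(outdir / MANIFEST_NAME)
    (outdir / MANIFEST_NAME).write_text(manifest.to_json())
    return manifest


def main(argv: list[str] | None = None) -> int:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    manifest = parse_args(argv)
    try:
        run_pipeline(manifest)
    except PipelineError as exc:
        logger.error("%s", exc)
        code = STAGE_EXIT_CODES.get(exc.stage, 1)
        sys.exit(code)
    for warning_text in manifest.warnings:
        logger.warning("%s", warning_text)
    logger.info("done; outputs in %s", manifest.outdir)
    return 0


if __name__ == "__main__":
    sys.exit(main())
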