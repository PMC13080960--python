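# pocketprep

Automated preparation of protein–ligand binding pockets for constrained
conformer–rotamer ensemble sampling (CREST). Starting from a protein PDB and
a posed ligand MOL2, the pipeline:

1. **Parses and preprocesses** the inputs — guesses missing element symbols
   from atom names, keeps a single alternate location per atom (altLoc blank
   or `A`), and extracts the ligand name from the MOL2 `SUBSTRUCTURE` /
   `ATOM` sections with fallbacks.
2. **Extracts the pocket** — all protein atoms within 3 Å of the ligand,
   grown in 0.5 Å steps until at least 70 atoms are found (at most 50
   attempts), completed to full residues, extended by 2.6 Å for cap-like
   terminal groups (excluding ligand and water), and cleaned of atoms with
   no neighbor within 1.9 Å. Ligands above 120 atoms are rejected up front.
3. **Cleans and protonates** — strips hydrogens, perceives covalent bonds,
   drops residues with no covalent link to another residue, and adds
   hydrogens at pH 7.4 through a pluggable backend (Open Babel when
   installed; a built-in valence-filling backend otherwise).
4. **Merges and charges** — concatenates pocket and ligand into the final
   PDB and computes the total formal charge by valence bookkeeping.
5. **Prepares the sampler run** — derives the 1-based indices of all
   non-ligand atoms, compresses them to range syntax (`1-6,8-10`), writes
   `constraints.inp` (xcontrol syntax), assembles the CREST command
   (defaults `--temp 310 --gfnff -squick`), and optionally executes it.
6. **Postprocesses** — converts the resulting multi-frame XYZ to
   `crest_conformers.pdb` and transfers the template's atom/residue
   metadata onto every frame in `crest_conformers_updated.pdb`, then
   deletes temporary files.

The package also ships a deterministic synthetic-complex generator
(`pocketprep.synthetic`) used by the test suite: it builds ligand-centered
protein shells with exact controlled distances plus real-world pathologies
(altLoc duplicates, blank element columns, stray atoms, floating residues,
waters), together with an explicit-loop brute-force oracle of the pocket
algorithm.

## CLI

```sh
pocketprep <protein_file.pdb> <ligand_file.mol2> <outdir> \
    [--no-crest] [--temp 310] [--lvl-of-theory gfnff] \
    [--extra-crest-arguments "-squick"] [--keep-altloc A] \
    [--protonation auto|openbabel|simple|none]
```

`outdir` is created as a subdirectory of the current working directory; all
outputs land inside it, including a machine-readable `run_manifest.json`.
Key outputs: `test_pocket_extended.pdb`, `final_structure.pdb`,
`constraints.inp`, and (when CREST runs) `crest_conformers.xyz`,
`crest_conformers.pdb`, `crest_conformers_updated.pdb`, `crest.out`.

## Tests

```sh
python -m pytest -q tests/
```

The suite runs entirely offline: CREST is replaced by a deterministic mock
runner and protonation by a stub backend. It includes property-based tests
(hypothesis) and an acceptance suite (`tests/test_acceptance.py`) that
recovers every pipeline constant by black-box boundary probing and checks
the vectorized pocket extraction against the brute-force oracle on 100
randomized synthetic complexes.

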