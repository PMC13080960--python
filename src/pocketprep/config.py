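"""Every numeric threshold and default of the pipeline, in one place."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline thresholds and defaults.

    The defaults are the published operating point of the workflow: a 3 A
    initial shell grown in 0.5 A steps until 70 atoms are reached (at most 50
    expansion attempts), a 120-atom ligand size gate, a 2.6 A cap extension,
    a 1.9 A isolated-atom cutoff, altLoc "A", protonation at pH 7.4 and the
    conformer-sampler defaults temp=310 / gfnff / -squick.
    """

    max_ligand_atoms: int = 120
    initial_radius: float = 3.0
    radius_step: float = 0.5
    min_pocket_atoms: int = 70
    max_expansion_attempts: int = 50
    cap_extension_radius: float = 2.6
    isolation_cutoff: float = 1.9
    keep_altloc: str = "A"
    protonation_pH: float = 7.4
    crest_temp: str = "310"
    crest_level: str = "gfnff"
    crest_extra: str = "-squick"
    water_res_names: frozenset[str] = field(
        default_factory=lambda: frozenset({"HOH", "WAT", "TIP3", "SOL"})
    )

    def __post_init__(self) -> None:
        for name in ("initial_radius", "radius_step", "cap_extension_radius",
                     "isolation_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("max_ligand_atoms", "min_pocket_atoms",
                     "max_expansion_attempts"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a strictly positive integer")
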