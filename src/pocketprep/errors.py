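"""Exception hierarchy for the pocket preparation pipeline."""


class PocketPrepError(Exception):
    """Base class for all package errors."""


class PdbParseError(PocketPrepError):
    """Raised when a PDB line cannot be parsed; message names the line number."""


class Mol2ParseError(PocketPrepError):
    """Raised when a TRIPOS MOL2 file is structurally invalid."""


class LigandSizeError(PocketPrepError):
    """Raised when the ligand is absent or exceeds the size gate."""


class ValenceError(PocketPrepError):
    """Raised (in strict mode) when formal-charge bookkeeping meets an
    impossible valence; message lists the offending atom serials."""


class ProtonationError(PocketPrepError):
    """Raised when a protonation backend is unavailable or fails."""


class ConstraintError(PocketPrepError):
    """Raised on invalid constraint specifications (e.g. empty atom set)."""


class CrestError(PocketPrepError):
    """Raised when the external conformer-sampler invocation fails."""


class EnsembleError(PocketPrepError):
    """Raised on malformed or inconsistent conformer ensembles."""


class FixtureError(PocketPrepError):
    """Raised when a synthetic-complex specification is geometrically infeasible."""


class PipelineError(PocketPrepError):
    """Stage-tagged failure of the end-to-end pipeline."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
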