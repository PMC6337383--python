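"""Exception hierarchy shared across the package."""


class SbpharmError(Exception):
    """Base class for all package errors."""


class SDFParseError(SbpharmError):
    """Raised when an SDF record cannot be parsed."""


class PDBParseError(SbpharmError):
    """Raised when a PDB coordinate record is malformed."""


class ModelValidationError(SbpharmError):
    """Raised when a pharmacophore model (or its JSON form) violates the schema."""


class EmptyModelError(SbpharmError):
    """Raised when feature perception yields no features at all."""


class DegenerateGeometryError(SbpharmError):
    """Raised when a point set is too degenerate for a rigid superposition."""


class MissingParameterError(SbpharmError):
    """Raised when force-field parameters are missing for one or more atoms."""


class StageError(SbpharmError):
    """Raised by the pipeline driver; carries the failing stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
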