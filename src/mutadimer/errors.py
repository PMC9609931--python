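"""Exception types shared across modules."""


class MutadimerError(Exception):
    """Base class for package errors."""


class PDBFormatError(MutadimerError):
    """Malformed or inconsistent PDB content (carries line/frame context)."""


class PairingError(MutadimerError):
    """Two structures or profiles could not be put in correspondence."""


class DegenerateGeometryError(MutadimerError):
    """Geometry is rank-deficient for the requested operation."""


class ConnectivityError(MutadimerError):
    """Elastic network is disconnected at the chosen cutoff."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class ManifestError(MutadimerError):
    """Pose manifest is inconsistent (duplicate ranks, missing files)."""


class ConsistencyError(MutadimerError):
    """Inputs computed with incompatible parameters were combined."""


class AtomTypingError(MutadimerError):
    """Atoms could not be assigned nonbonded parameters."""

    def __init__(self, message, atoms=None):
        super().__init__(message)
        self.atoms = atoms or []


class ConfigError(MutadimerError):
    """Invalid user configuration (rules, orientations, models)."""


class InputError(MutadimerError):
    """Invalid tabular input (duplicate ids, missing columns)."""


class GenerationError(MutadimerError):
    """A synthetic generator failed to satisfy its own constraints."""
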