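"""Exception types raised across the package."""


class PromabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PromabError, ValueError):
    """Invalid generator or analysis configuration."""


class InputError(PromabError, ValueError):
    """Invalid user-supplied data (sequences, regions, selections)."""


class PairingError(InputError):
    """Heavy/light chain pairing in a FASTA file is inconsistent."""


class ExtractionError(InputError):
    """A CDR anchor motif could not be located."""


class EnsembleFormatError(InputError):
    """A multi-model PDB file violates the shared-roster contract."""


class GenerationError(PromabError, RuntimeError):
    """The constraint-respecting ensemble generator failed to satisfy
    its bond-length tolerance."""
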