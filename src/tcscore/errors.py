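"""Exception hierarchy shared across the package."""


class TCScoreError(Exception):
    """Base class for all package errors."""


class RepertoireFormatError(TCScoreError, ValueError):
    """A clonotype table does not conform to a recognized dialect."""


class EmptyRepertoireError(TCScoreError, ValueError):
    """No productive clonotypes survive filtering, or an empty sample was given."""


class ConfigurationError(TCScoreError, ValueError):
    """An unknown mode, formula, or inconsistent configuration value."""


class InvalidSequenceError(TCScoreError, ValueError):
    """A CDR3 string contains characters outside the 20 standard amino acids."""


class DataError(TCScoreError, ValueError):
    """Input data violates a precondition (empty window, single class, ...)."""
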