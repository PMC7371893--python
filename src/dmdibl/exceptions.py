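"""Exception hierarchy for dmdibl."""


class DmdiblError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DmdiblError):
    """A model parameter is outside its declared range."""


class VocabularyError(DmdiblError):
    """A slot value is not part of the declared vocabulary."""


class NoHistoryError(DmdiblError):
    """Base-level activation requested for an instance with no retrieval history."""


class ContractError(DmdiblError):
    """An internal invariant was violated (e.g. a retrieval event in the future)."""


class RetrievalError(DmdiblError):
    """Retrieval attempted against an empty memory store."""


class ConfigError(DmdiblError):
    """Invalid task, grid or generator configuration."""


class AlignmentError(DmdiblError):
    """Model and human score tables do not cover the same sheets/measures."""


class CoordinateError(DmdiblError):
    """A mutation record has exon coordinates outside the valid 1-79 range."""


class ShapeError(DmdiblError):
    """A recall grid does not have the expected 5 x 15 binary shape."""
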