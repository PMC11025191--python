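"""Exception hierarchy for ndminer."""


class NdminerError(Exception):
    """Base class for all ndminer errors."""


class SchemaError(NdminerError):
    """A tabular input is missing required columns or keys."""


class RecordValidationError(NdminerError):
    """A publication record or corpus violates an invariant."""


class DuplicatePmidError(RecordValidationError):
    """Two records in one corpus share a PMID."""


class CorpusParseError(NdminerError):
    """A corpus file could not be parsed."""


class ConfigError(NdminerError):
    """A vocabulary or pipeline configuration file is invalid."""


class ProfileStateError(NdminerError):
    """A profile operation was applied in the wrong state (e.g. double filtering)."""


class GeneNotFoundError(NdminerError, KeyError):
    """A requested gene symbol is absent from the available summaries."""


class PlantCollisionError(NdminerError):
    """Synthetic corpus text accidentally matches a concept that was not planted."""
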