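"""Exception hierarchy shared across the package."""


class LocinferError(Exception):
    """Base class for all package-specific errors."""


class GazetteerFormatError(LocinferError):
    """Gazetteer file is structurally invalid (missing columns, bad level)."""


class GazetteerConflictError(LocinferError):
    """A surface form or canonical name maps to two units at one level."""


class GazetteerReferentialError(LocinferError):
    """A city row references a parent province that does not exist."""


class GazetteerLookupError(LocinferError):
    """An AdminUnit was queried against a gazetteer it does not belong to."""


class CorpusParseError(LocinferError):
    """A corpus record is malformed; the message names the line number."""


class ExtractorError(LocinferError):
    """An extractor adapter failed; the message names the offending post."""


class TrainingError(LocinferError):
    """HMM training received an empty or unusable training set."""


class TagValidationError(LocinferError):
    """A training sample has an invalid tag sequence; names the sample."""


class ConsistencyError(LocinferError):
    """A mention references a post absent from the corpus."""


class ConfigurationError(LocinferError):
    """An invalid pipeline configuration (unknown method, <2 voters, ...)."""


class EvaluationError(LocinferError):
    """Gold labels and predictions are inconsistent or gold is empty."""


class GenerationError(LocinferError):
    """The synthetic-corpus generator received invalid parameters."""
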