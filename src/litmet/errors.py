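"""Exception hierarchy for the litmet pipeline."""


class LitmetError(Exception):
    """Base class for all litmet errors."""


class EmbeddingFormatError(LitmetError):
    """Malformed word2vec text file (bad header, row arity, empty file)."""


class ZeroVectorError(EmbeddingFormatError):
    """A vector with zero Euclidean norm was encountered at load time."""


class VocabularyError(LitmetError, KeyError):
    """A queried word is not in the lexicon vocabulary."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"word not in vocabulary: {self.word!r}"


class ParameterError(LitmetError, ValueError):
    """Invalid predication or simulation parameters."""


class NormalizationError(LitmetError, ValueError):
    """Z-normalization impossible (e.g. zero variance in a measure)."""

    def __init__(self, measure: str, message: str | None = None):
        self.measure = measure
        super().__init__(message or f"cannot normalize measure {measure!r}: zero variance")


class SizingError(LitmetError, ValueError):
    """A selection or matching request exceeds the available pool."""


class DataError(LitmetError, ValueError):
    """Trial-level data violate a precondition (missing accuracy, bad RTs...)."""


class DependencyError(LitmetError):
    """A pipeline stage was requested without its required input artifacts."""


class ConfigError(LitmetError, ValueError):
    """Invalid or unknown pipeline configuration keys."""
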