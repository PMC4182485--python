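"""Exception types shared across the package."""


class SeedAtlasError(Exception):
    """Base class for all seedatlas errors."""


class AlphabetError(SeedAtlasError, ValueError):
    """A sequence contains characters outside the ACGU/ACGT alphabet."""


class NoAnchorError(SeedAtlasError):
    """No 5p/3p anchor pair within the mismatch tolerance.

    ``best_distance`` carries the smallest total Hamming distance found over
    all geometrically valid offset pairs (or ``None`` if none exist).
    """

    def __init__(self, message, best_distance=None):
        super().__init__(message)
        self.best_distance = best_distance


class OutOfBoundsError(SeedAtlasError, IndexError):
    """A mature/seed window falls outside the hairpin sequence."""


class CodeUndefinedError(SeedAtlasError):
    """The seed window no longer overlaps the conserved block, so no
    block-relative seed code exists for the designation."""


class ParseError(SeedAtlasError, ValueError):
    """A seed code or isomiR name is malformed."""


class MalformedRecordError(SeedAtlasError, ValueError):
    """An input sequencing record could not be interpreted."""

    def __init__(self, message, record_index=None):
        super().__init__(message)
        self.record_index = record_index


class MissingConditionError(SeedAtlasError):
    """An activity call cannot be resolved from the supplied outcome matrix.

    ``missing`` lists (reporter_id, condition) pairs whose measurement would
    resolve the call.
    """

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class DefinitionMismatchError(SeedAtlasError, ValueError):
    """Two seed repertoires built under different seed definitions were
    compared."""
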