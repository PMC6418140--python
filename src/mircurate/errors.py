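"""Exception hierarchy for mircurate.

All pipeline-facing errors derive from :class:`MircurateError` so callers can
catch one base class at the CLI boundary.
"""


class MircurateError(Exception):
    """Base class for all mircurate errors."""


class StructureFormatError(MircurateError):
    """Dot-bracket string is unbalanced or contains an illegal character.

    Carries ``index``, the 0-based offending position.
    """

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (index {index})")
        self.index = index


class NotADuplexError(MircurateError):
    """Mature interval spans the terminal loop; no duplex partner exists."""


class TruncatedPrecursorError(MircurateError):
    """Inferred star interval would extend past the precursor boundary."""


class InvalidDuplexError(MircurateError):
    """Mature/star intervals overlap or are not on opposite arms."""


class UndefinedEvidenceError(MircurateError):
    """A read-stack metric is undefined (e.g. zero total counts)."""


class UndefinedReferenceError(MircurateError):
    """isomiR reference (mature/star) has zero supporting reads."""


class ParameterError(MircurateError):
    """Simulation or threshold parameters are infeasible."""


class ConfigError(MircurateError):
    """Pipeline configuration is missing inputs or malformed."""


class FastqFormatError(MircurateError):
    """Malformed FASTQ record; carries the record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"{message} (record {record_index})")
        self.record_index = record_index
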