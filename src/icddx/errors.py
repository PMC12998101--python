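"""Exception hierarchy for the icddx package.

Every error raised deliberately by the library derives from
:class:`IcddxError`, so callers (and the CLI) can catch one type.
"""


class IcddxError(Exception):
    """Base class for all icddx errors."""


class InvalidCodeError(IcddxError):
    """A raw code string is empty or otherwise un-normalizable."""


class UnknownCodeError(IcddxError):
    """A (normalized) code is not present in the taxonomy."""


class DuplicateCodeError(IcddxError):
    """A taxonomy source defines the same code twice."""


class MissingParentError(IcddxError):
    """A taxonomy row references a parent code never defined in the source."""


class LevelInconsistencyError(IcddxError):
    """A node's level rank is not exactly its parent's rank plus one."""


class FormatError(IcddxError):
    """A tabular input file violates its documented dialect."""


class MissingLabelError(IcddxError):
    """A record lacks the expert reference label required for validation."""


class MissingCategoryError(IcddxError):
    """A false-positive record lacks the rating category needed for the audit."""


class DegenerateLabelsError(IcddxError):
    """ROC analysis was asked for with only one class present."""


class GenerationError(IcddxError):
    """The synthetic-cohort generator cannot satisfy the requested structure."""
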