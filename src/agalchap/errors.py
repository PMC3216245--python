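"""Exception hierarchy for agalchap.

All package-raised errors derive from :class:`AgalChapError` so callers can
catch one type at an application boundary (the CLI does exactly that).
"""


class AgalChapError(Exception):
    """Base class for all errors raised by agalchap."""


class FormatError(AgalChapError):
    """A file does not conform to its expected on-disk layout."""


class EmptyInputError(AgalChapError):
    """An input file or collection contained no usable records."""


class ParseError(AgalChapError):
    """A mutation string could not be parsed."""


class ValidationError(AgalChapError):
    """A parsed value violates a domain invariant."""


class FixtureIntegrityError(AgalChapError):
    """A packaged data table does not match its recorded checksum/shape."""


class CoordinateError(AgalChapError):
    """A protein position falls outside the scoring matrix."""


class ReferenceMismatchError(AgalChapError):
    """The stated wild-type residue disagrees with the matrix query."""


class ConfigurationError(AgalChapError):
    """Profile-construction parameters are inconsistent."""


class UndefinedStatisticError(AgalChapError):
    """A statistic is undefined for the given input (empty panel, zero variance)."""
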