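"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2,
data/format problems exit 3.
"""


class EpicrosstalkError(Exception):
    """Base class for all package errors."""


class ConfigError(EpicrosstalkError, ValueError):
    """A parameter or configuration value is out of its documented range."""


class FormatError(EpicrosstalkError, ValueError):
    """An input file violates its format contract (structure, not values)."""


class DataError(EpicrosstalkError, ValueError):
    """An input value violates a domain invariant (e.g. negative FPKM)."""


class AlignmentError(EpicrosstalkError, ValueError):
    """Sample identifiers of two objects do not line up."""


class DegenerateModuleError(EpicrosstalkError, ValueError):
    """A gene set is too small or too degenerate to summarize as an eigengene."""


class InsufficientDataError(EpicrosstalkError, ValueError):
    """Too few observations to fit the requested model."""
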