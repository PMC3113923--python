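"""Exception hierarchy.

All package-raised errors derive from :class:`MetmemError` so callers can
catch everything with one clause; subclasses distinguish bad files from
bad data from bad configuration (the CLI maps these onto exit codes).
"""


class MetmemError(Exception):
    """Base class for all errors raised by metmem."""


class FormatError(MetmemError):
    """A file does not conform to its declared dialect (bad header, bad field)."""


class IntegrityError(MetmemError):
    """Structurally valid input that violates a data contract
    (duplicate probe ids, sample without a control-gene well, ...)."""


class ConfigError(MetmemError, ValueError):
    """Invalid parameter combination (proportions not summing to one, ...)."""


class ContractError(MetmemError):
    """An operation was called outside its stated precondition."""


class UndefinedCorrelationError(MetmemError, ValueError):
    """Pearson correlation requested on a zero-variance vector."""
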