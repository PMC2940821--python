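"""Exception hierarchy."""


class BoolsigError(Exception):
    """Base class for all package-specific errors."""


class MidasFormatError(BoolsigError, ValueError):
    """A MIDAS-dialect CSV file violates the format contract."""


class MissingConditionError(BoolsigError, LookupError):
    """A (protein, condition, time) lookup failed."""


class ContractError(BoolsigError, RuntimeError):
    """An operation was called outside its stated precondition."""
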