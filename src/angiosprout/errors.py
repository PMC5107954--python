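"""Exception hierarchy."""


class AngiosproutError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AngiosproutError):
    """Invalid simulation configuration (the message names the offending field)."""


class OutOfDomainError(AngiosproutError):
    """A position falls outside the simulation domain."""


class IllegalOperationError(AngiosproutError):
    """An operation was requested on an object whose state forbids it."""
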