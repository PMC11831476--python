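"""Exception hierarchy shared across the package."""


class WormCircuitError(Exception):
    """Base class for all package errors."""


class FormatError(WormCircuitError):
    """A file does not conform to the expected tabular/JSON layout."""


class ValidationError(WormCircuitError):
    """Input values violate a documented precondition or invariant."""


class IntegrityError(WormCircuitError):
    """A packaged fixture failed its checksum."""


class UsageError(WormCircuitError):
    """An unknown option, strategy, or name was requested."""
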