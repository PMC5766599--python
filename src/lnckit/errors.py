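"""Exception hierarchy used across the package.

All anticipated failure modes raise a subclass of :class:`LnckitError`
so callers can distinguish pipeline errors from programming bugs.
"""


class LnckitError(Exception):
    """Base class for every error this package raises deliberately."""


class ConfigurationError(LnckitError):
    """An invalid configuration value; the message names the field."""


class ParseError(LnckitError):
    """A file could not be parsed; includes row/column coordinates when known."""


class ValidationError(LnckitError):
    """A parsed object violates an invariant (duplicate ids, bad vocabulary...)."""


class PairingError(ValidationError):
    """A sample sheet cannot be interpreted as a matched tumor/normal design."""


class FitError(LnckitError):
    """A model fit or optimisation failed in a way that is not a user error."""
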