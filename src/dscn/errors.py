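"""Exception hierarchy shared by all dscn modules.

Exit-code convention for the CLI: 0 = success, 1 = user/input problem,
2 = internal failure.
"""


class DscnError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class InputError(DscnError):
    """The supplied data cannot be used (empty, inconsistent, missing genes...)."""

    exit_code = 1


class FormatError(InputError):
    """A file could not be parsed as the expected table format."""


class DegenerateInputError(InputError):
    """Data is syntactically fine but degenerate for the requested operation."""


class ConfigError(DscnError):
    """Unknown scheme/scope/option or malformed configuration."""

    exit_code = 1


class InternalError(DscnError):
    """Invariant violated inside the package; a bug, not a user error."""
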