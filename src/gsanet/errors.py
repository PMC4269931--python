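"""Exception hierarchy shared across the package.

The CLI maps these onto its exit-code contract: data problems
(:class:`InputError`, :class:`ValidationError`) exit 1, caller mistakes
(:class:`UsageError`) exit 2.
"""


class GsanetError(Exception):
    """Base class for all package errors."""


class InputError(GsanetError):
    """An input file is absent or unreadable."""


class ValidationError(GsanetError):
    """An input file was read but its content violates the format contract."""


class UsageError(GsanetError):
    """The caller asked for something the API does not offer (bad dialect,
    unknown column, out-of-range parameter)."""
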