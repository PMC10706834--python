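"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`InputError` (and subclasses) to exit code 2 and
:class:`QuantificationFailure` to exit code 3.
"""


class SalmoquantError(Exception):
    """Base class for all package errors."""


class InputError(SalmoquantError, ValueError):
    """Invalid user-supplied value or malformed input."""


class FormatError(InputError):
    """Malformed delimited file or config; carries line context when known."""


class SaturationError(SalmoquantError):
    """Every droplet positive: lambda is unbounded and no estimate exists."""


class QuantificationFailure(SalmoquantError):
    """No usable wells remain, so a sample cannot be quantified."""
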