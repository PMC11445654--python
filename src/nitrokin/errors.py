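"""Exception hierarchy.

CLI exit-code convention: schema/validation errors exit 2, fit failures
exit 3, calibration-envelope violations exit 4.
"""


class NitrokinError(Exception):
    """Base class for all package errors."""


class RangeError(NitrokinError, ValueError):
    """An input lies outside the supported range of a bundled correlation."""


class SchemaError(NitrokinError, ValueError):
    """A file or table violates its documented schema."""


class FitError(NitrokinError, RuntimeError):
    """A regression is underdetermined or produced a non-physical result."""


class EnvelopeError(NitrokinError, ValueError):
    """A requested condition violates the hard calibration envelope."""
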