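"""Exception hierarchy for maculamap."""


class MaculamapError(Exception):
    """Base class for all package errors."""


class SchemaError(MaculamapError):
    """Interchange metadata is missing a field or a field has the wrong type.

    The message always names the offending field.
    """


class StructuralError(MaculamapError):
    """Arrays that must agree in shape do not (e.g. boundary matrices)."""


class ValidationError(MaculamapError):
    """A domain invariant is violated (boundary ordering, negative scale, ...).

    Where the violation is localised, the message carries the (bscan, ascan)
    coordinate of the first offending sample.
    """


class UnsupportedInputError(MaculamapError):
    """Input is well-formed but outside the supported envelope
    (e.g. too few B-scans for bicubic interpolation)."""


class ConfigError(MaculamapError):
    """Run configuration is invalid; the message names the offending key."""
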