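"""Exception types shared across the package."""


class LemnormError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LemnormError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class IntegrityError(LemnormError, ValueError):
    """Input data violates a structural invariant (e.g. duplicate record keys)."""


class ParameterError(LemnormError, ValueError):
    """An argument is outside its admissible range."""


class MissingDataError(LemnormError, ValueError):
    """An operation requiring a complete matrix met missing cells."""
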