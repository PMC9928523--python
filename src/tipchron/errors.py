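"""Exception hierarchy shared across the package."""


class TipchronError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TipchronError, ValueError):
    """A file or serialized object violates its expected format."""


class ParameterError(TipchronError, ValueError):
    """A model or operation parameter is outside its valid range."""


class TreeConstraintError(TipchronError, ValueError):
    """A time tree violates its age-ordering invariants."""
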