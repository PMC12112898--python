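"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class SchemaError(RefstabError, ValueError):
    """A required column or field is missing or misnamed."""


class ParseError(RefstabError, ValueError):
    """A file could not be parsed (ragged rows, empty input, bad values)."""


class ValidationError(RefstabError, ValueError):
    """Parsed data violates an invariant (range, sign, uniqueness)."""


class EstimationError(RefstabError, RuntimeError):
    """A statistical quantity cannot be estimated from the given data."""
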