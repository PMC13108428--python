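"""Package-wide exception types."""


class PainECGError(Exception):
    """Base class for all package errors."""


class ValidationError(PainECGError, ValueError):
    """An input violated a documented invariant (e.g. CoVAS outside 0-100)."""


class FormatError(PainECGError, ValueError):
    """A file did not match the documented on-disk contract."""
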