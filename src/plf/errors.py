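"""Exception hierarchy shared across the package."""


class PLFError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PLFError):
    """A file does not conform to its declared format."""


class ValidationError(PLFError):
    """Input is well-formed but violates a domain invariant."""
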