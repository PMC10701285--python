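"""Exception hierarchy shared across the package."""


class CttkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CttkitError):
    """A file could not be parsed (bad header, wrong dialect, empty file)."""


class ValidationError(CttkitError):
    """Parsed content violates an invariant (duplicate ids, bad values)."""


class ParameterError(CttkitError):
    """A caller-supplied parameter is outside its admissible range."""
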