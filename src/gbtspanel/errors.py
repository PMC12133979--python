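"""Exception hierarchy for the gbtspanel toolkit."""


class GbtsPanelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GbtsPanelError, ValueError):
    """An object or table violates a structural invariant."""


class FormatError(GbtsPanelError):
    """A file could not be parsed in the expected format."""


class UnsupportedRecordError(FormatError):
    """A record is syntactically valid but outside the supported subset
    (e.g. a multi-allelic VCF record)."""


class CapacityError(GbtsPanelError, ValueError):
    """A simulation request exceeds what the configuration can hold
    (e.g. more sites than available positions on a chromosome)."""


class DefinitionError(GbtsPanelError, ValueError):
    """A trait-marker definition references data that is not available."""


class ParameterError(GbtsPanelError, ValueError):
    """A numeric parameter is outside its legal range."""
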