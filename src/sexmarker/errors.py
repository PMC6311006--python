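"""Exception hierarchy."""


class SexMarkerError(Exception):
    """Base class for all package errors."""


class ValidationError(SexMarkerError):
    """Invalid in-memory object state or parameter value."""


class GenotypeParseError(SexMarkerError):
    """A text token or file record could not be parsed."""


class PrimerDesignError(SexMarkerError):
    """No primer placement satisfies the requested constraints."""
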