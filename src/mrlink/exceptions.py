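"""Exceptions shared across the package."""


class MRLinkError(Exception):
    """Base class for package errors."""


class NoInstrumentsError(MRLinkError):
    """Raised when instrument selection or harmonization leaves no usable SNPs."""


class InputError(MRLinkError):
    """Raised for malformed or unusable input tables."""
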