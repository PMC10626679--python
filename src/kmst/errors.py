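"""Typed exceptions and warnings shared across the package."""


class KmstError(Exception):
    """Base class for all package errors."""


class InvalidBaseError(KmstError):
    """A sequence contains a character outside {A, C, G, T}."""


class LengthError(KmstError):
    """A k-mer string does not have the configured length k."""


class EmptyInputError(KmstError):
    """An operation received an empty read collection or k-mer set."""


class ParameterError(KmstError):
    """A numeric parameter is out of its valid range."""


class DuplicateSampleError(KmstError):
    """Two samples in a collection share the same sample id."""


class MetadataError(KmstError):
    """A sample is missing a label or group annotation."""


class UnknownClassError(KmstError):
    """A sample label is not a member of the configured class order."""


class FormatError(KmstError):
    """A serialized matrix or metadata file violates the TSV dialect."""


class ShapeError(KmstError):
    """Matrix/vector dimensions do not agree."""


class ConfigError(KmstError):
    """A simulation configuration is internally inconsistent."""


class NoMatchWarning(UserWarning):
    """A sink shares no k-mer with any source; proportions are undefined."""
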