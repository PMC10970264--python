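"""Exception hierarchy.

``PlastotypeError`` is the root; the CLI maps ``ConfigError`` to exit code 1
and ``DataError`` subclasses to exit code 2.
"""


class PlastotypeError(Exception):
    """Base class for all package errors."""


class ConfigError(PlastotypeError):
    """Invalid configuration value or combination."""


class DataError(PlastotypeError):
    """Invalid or inconsistent input data."""


class AlignmentError(DataError):
    """Sequences that do not form a valid alignment."""


class MetadataError(DataError):
    """Sample sheet inconsistent with sequence data."""


class FormatError(DataError):
    """A file does not conform to its expected dialect."""


class CoordinateError(DataError):
    """A feature lies outside the coordinate system it refers to."""


class EncodingError(DataError):
    """A variant cannot be expressed in the requested representation."""


class CapacityError(ConfigError):
    """A simulation request exceeds what the genome length admits."""


class StructureNotFoundError(DataError):
    """No inverted-repeat pair of the required size exists."""


class InsufficientDataError(DataError):
    """Too few non-missing observations for an estimator."""


class MonomorphicLocusError(DataError):
    """F_st is undefined at a locus with a single allele."""


class UncoveredGroupError(DataError):
    """Panel selection cannot cover one or more groups."""


class PanelError(DataError):
    """A panel and the data it is applied to do not match."""


class NoDesignError(DataError):
    """No primer satisfying the thermodynamic constraints exists."""
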