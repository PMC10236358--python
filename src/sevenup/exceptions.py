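"""Exception hierarchy; every contract violation raises a subclass of SevenUpError."""


class SevenUpError(Exception):
    """Base class for all package errors."""


class DimensionMismatchError(SevenUpError):
    """Images, masks or feature matrices that must be aligned are not."""


class MissingMarkerError(SevenUpError):
    """A marker named in a manifest is absent from a container or table."""


class DuplicateKeyError(SevenUpError):
    """Duplicate (sample_id, cell_label) rows encountered."""


class CorruptBundleError(SevenUpError):
    """A model bundle archive is unreadable, truncated, or version-incompatible."""


class DegenerateDispersionError(SevenUpError):
    """A marker has zero dispersion within a sample; z-scoring is undefined."""


class NoCellsError(SevenUpError):
    """A segmentation mask contains no labeled cells."""


class UndefinedCorrelationError(SevenUpError):
    """A correlation is requested on a zero-variance vector."""


class PackingError(SevenUpError):
    """Synthetic cells could not be placed without overlap within the retry cap."""


class AnnotationError(SevenUpError):
    """A cluster id has no cell-type annotation."""
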