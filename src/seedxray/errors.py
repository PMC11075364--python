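"""Exception hierarchy for the seedxray pipeline.

Every error raised on purpose by the package derives from
:class:`SeedXrayError`, so callers (and the CLI) can catch one type.
"""


class SeedXrayError(Exception):
    """Base class for all seedxray errors."""


class AnnotationError(SeedXrayError):
    """Malformed or unparseable annotation input (VOC XML / YOLO text)."""


class BoxValidationError(SeedXrayError):
    """A bounding box violates the internal half-open convention or image bounds."""


class CatalogError(SeedXrayError):
    """Unknown class label or class index outside the catalog."""


class EmptyMaskError(SeedXrayError):
    """Segmentation produced no foreground for a crop."""


class ConfigurationError(SeedXrayError):
    """Invalid pipeline or operation configuration."""


class SizeError(SeedXrayError):
    """Input too small / counts inconsistent for the requested operation."""


class LayoutOverflowError(SeedXrayError):
    """A crop does not fit the layout cell it was assigned to."""


class ParameterError(SeedXrayError):
    """A numeric parameter outside its admissible range."""


class FixtureDriftError(SeedXrayError):
    """A regenerated fixture no longer matches its registered checksum."""
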