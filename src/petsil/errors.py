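"""Exception hierarchy for the pipeline."""


class PetsilError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PetsilError):
    """A configuration field is invalid; the message names the field."""


class DegenerateVOIError(PetsilError):
    """A volume of interest is too small or empty for the requested operation."""


class TextureUndefinedError(PetsilError):
    """A texture matrix has no valid voxel pairs / neighbourhoods."""


class EmbeddingDegenerateError(PetsilError):
    """All features are constant; no embedding axis exists."""


class SilhouetteUndefinedError(PetsilError):
    """Fewer than two patients (labels) present; silhouette is undefined."""


class TestUndefinedError(PetsilError):
    """A statistical test has too few paired/grouped observations."""

    __test__ = False  # not a pytest class despite the name


class SplitError(PetsilError):
    """A clinical split produced an empty or invalid group."""


class ValidationError(PetsilError):
    """A table failed schema validation; the message names row and column."""
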