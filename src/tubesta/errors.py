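"""Exception hierarchy shared across the package."""


class TubestaError(Exception):
    """Base class for all package errors."""


class FormatError(TubestaError):
    """A file on disk is not in the expected format."""


class SchemaError(TubestaError):
    """A particle table is missing columns or violates an invariant."""


class ValidationError(TubestaError):
    """An argument violates an operation's precondition."""


class GeometryError(TubestaError):
    """A geometric construction is undefined for the given input."""


class ExtractionError(TubestaError):
    """A subtomogram crop would fall outside its tomogram."""


class DegenerateInputError(TubestaError):
    """A volume has zero variance under the correlation mask."""


class ConfigError(TubestaError):
    """A run configuration is missing or inconsistent."""


class PipelineError(TubestaError):
    """A pipeline stage failed; message names the stage."""
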