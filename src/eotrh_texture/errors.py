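"""Exception hierarchy for the EOTRH texture pipeline."""


class EotrhTextureError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EotrhTextureError):
    """Unsupported or malformed image/table on disk (wrong channels, depth, header)."""


class ConfigError(EotrhTextureError):
    """Invalid configuration (bad parameter value, infeasible cohort counts, duplicate filters)."""


class MissingGradeError(EotrhTextureError):
    """A mask label has no matching grade record."""


class EmptyROIError(EotrhTextureError):
    """A region of interest has no (or too few) foreground pixels."""


class DegenerateInputError(EotrhTextureError):
    """Input degenerate for the requested operation (e.g. normalizing a constant image)."""
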