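"""Exception hierarchy for the hematrisk pipeline."""


class HematriskError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(HematriskError):
    """A printed summary cell cannot be converted into distribution parameters."""


class ConfigError(HematriskError):
    """Inconsistent cohort or pipeline configuration."""


class DimensionError(HematriskError):
    """Vector/matrix shape mismatch."""


class ParameterError(HematriskError):
    """Out-of-range argument (e.g. cut level, subset size)."""


class DegenerateInputError(HematriskError):
    """Input too small or too uniform for the requested operation."""


class SchemaError(HematriskError):
    """A required column or category is missing from a clinical table."""


class EvaluationError(HematriskError):
    """A classifier cannot be trained on the requested subpopulation."""


class ParseError(HematriskError):
    """Malformed input file."""
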