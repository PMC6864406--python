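"""Exception hierarchy shared across the pipeline."""


class GlyscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(GlyscreenError, ValueError):
    """Invalid argument or configuration value."""


class SchemaError(GlyscreenError):
    """An input table is missing a required column or has an unparsable cell."""


class DegenerateTableError(ValidationError):
    """A 2x2 contingency table with a zero margin; the statistic is undefined."""


class MissingCovariateError(GlyscreenError):
    """A patient lacks every measurement of a required covariate."""
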