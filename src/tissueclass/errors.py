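"""Exception hierarchy shared across the pipeline.

All domain failures derive from :class:`TissueClassError` so callers (and the
CLI) can separate data problems from programming errors.
"""


class TissueClassError(Exception):
    """Base class for all tissueclass domain errors."""


class FormatError(TissueClassError):
    """A file violates its declared tabular format (duplicates, empty, bad header)."""


class MatrixValueError(TissueClassError):
    """A matrix cell is negative, missing, or non-numeric."""


class MappingError(TissueClassError):
    """A sample or tissue cannot be resolved through a manifest or mapping."""


class ConfigurationError(TissueClassError):
    """Parameters are invalid or infeasible for the requested operation."""


class InputError(TissueClassError):
    """Inputs to an analysis are structurally inconsistent (duplicate ids, mismatched gene sets)."""


class StatisticsError(TissueClassError):
    """A statistical comparison cannot be computed (e.g. an empty group)."""
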