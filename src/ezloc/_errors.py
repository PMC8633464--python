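"""Exception hierarchy.

Schema/validation/configuration problems and computation-time problems are
kept on separate branches so the CLI can map them to distinct exit codes.
"""


class EzlocError(Exception):
    """Base class for all package errors."""


class SchemaError(EzlocError):
    """The input file does not conform to the cohort schema."""


class DuplicationError(SchemaError):
    """A (patient, rater, roi) key appears more than once."""


class CohortValidationError(EzlocError):
    """A structurally well-formed table violates a cohort invariant."""


class ConfigError(EzlocError):
    """A simulation or pipeline configuration is invalid."""


class PlantingError(ConfigError):
    """A rule cannot be planted into a synthetic cohort."""


class AlignmentError(EzlocError):
    """Two collections that must share keys do not."""


class UndefinedMetricError(EzlocError):
    """A statistic is undefined for the given input (degenerate margins)."""


class EmptyCohortError(EzlocError):
    """An analysis was requested on an empty patient set."""
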