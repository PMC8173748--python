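"""Exception hierarchy for dwiresponse."""


class DwiResponseError(Exception):
    """Base class for all package errors."""


class InvalidSignalError(DwiResponseError):
    """Signal intensities violate a precondition (non-positive, non-finite)."""


class SchemeError(DwiResponseError):
    """B-value scheme is inconsistent (ordering, subset membership, length)."""


class InsufficientDataError(DwiResponseError):
    """Too few usable data points for the requested fit or test."""


class GridError(DwiResponseError):
    """Volume / mask / map shapes do not share a common voxel grid."""


class ConfigurationError(DwiResponseError):
    """Invalid configuration value (unknown model id, infeasible bounds, ...)."""


class IntegrityError(DwiResponseError):
    """Input table violates an integrity constraint (duplicate keys, ...)."""


class UnsupportedSampleError(DwiResponseError):
    """Sample size outside the supported range of a statistical routine."""


class UndefinedTableError(DwiResponseError):
    """Contingency table with an all-zero margin."""


class UndefinedRocError(DwiResponseError):
    """ROC is undefined (single-class labels)."""


class PairingError(DwiResponseError):
    """Paired-score comparison received unpaired inputs."""
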