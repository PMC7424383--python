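"""Exception hierarchy shared across the package.

Every reader rejects malformed input with one of these instead of silently
coercing, so a pipeline failure always names the offending stage.
"""


class CernaError(Exception):
    """Base class for all package errors."""


class FormatError(CernaError):
    """Malformed input file: bad header, duplicate ids, non-numeric cells."""


class ValidationError(CernaError):
    """Well-formed input violating a domain invariant (e.g. time <= 0)."""


class MappingError(CernaError):
    """A sample is missing from the supplied sample -> group mapping."""


class ConsistencyError(CernaError):
    """Contradictory records, e.g. one target id under two RNA classes."""


class ConfigError(CernaError):
    """Invalid run configuration or infeasible simulation sizes."""


class NormalizationError(CernaError):
    """Normalization impossible, e.g. an all-zero library."""


class DegenerateSplitError(CernaError):
    """Median split requested on a constant variable."""


class CollinearityError(CernaError):
    """Cox design matrix is singular; message names the offending feature."""


class ConvergenceError(CernaError):
    """Newton-Raphson failed to converge (monotone likelihood / separation)."""


class EmptyNetworkError(CernaError):
    """No ceRNA pair survived the filters, so there is no network to build."""


class ScoringError(CernaError):
    """A pair score (e.g. regulation similarity) is undefined for this input."""
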