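"""Exception hierarchy shared across the package."""


class GscoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GscoreError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(GscoreError):
    """Input content violates a stated invariant."""


class AlleleMismatchError(GscoreError):
    """Allele pairs of the same SNP cannot be reconciled between two sources."""


class EmptyInstrumentError(GscoreError):
    """No usable instrument SNPs remain after matching/filtering."""


class DegenerateScoreError(GscoreError):
    """The computed score has zero variance and cannot be standardized."""


class DegenerateVarianceError(GscoreError):
    """An allele frequency of 0 or 1 makes the per-SNP variance zero."""


class InsufficientSamplesError(GscoreError):
    """Fewer samples than the operation requires."""


class ConvergenceError(GscoreError):
    """An iterative fit failed to converge (e.g. perfect separation)."""


class CollinearityError(GscoreError):
    """A design matrix is rank deficient or numerically singular."""


class ConfigError(GscoreError):
    """A configuration object is internally inconsistent or infeasible."""
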