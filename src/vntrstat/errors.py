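"""Exception hierarchy.

Every error raised on a scientific precondition violation derives from
:class:`VntrStatError` so callers (and the CLI) can distinguish bad input
from genuine bugs.
"""


class VntrStatError(Exception):
    """Base class for all package errors."""


class MonomorphicSNPError(VntrStatError):
    """A genotype column has zero variance and cannot be normalized."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            f"monomorphic (zero-variance) SNP column(s): {', '.join(self.snp_ids)}"
        )


class CollinearityError(VntrStatError):
    """The normalized design matrix is rank deficient."""


class InsufficientSampleError(VntrStatError):
    """Fewer training samples than predictors."""


class NoUsableSNPsError(VntrStatError):
    """SNP sets of two inputs have an empty intersection."""


class AlleleMismatchError(VntrStatError):
    """Allele pair cannot be reconciled by flipping or strand complement."""


class IncompatiblePanelsError(VntrStatError):
    """Panels cannot be merged (SNP sets, alleles, or duplicate samples)."""


class DegenerateWeightsError(VntrStatError):
    """The quadratic form K_wv = w'Vw is numerically zero."""


class DegeneratePredictorError(VntrStatError):
    """Predicted VNTR dosage is constant; regression undefined."""


class ConfigError(VntrStatError):
    """Invalid simulation or run configuration."""


class InfeasibleVarianceError(ConfigError):
    """Requested effect plus covariate variance exceeds total phenotype variance."""


class SchemaError(VntrStatError):
    """An input file does not match the expected schema."""


class FixtureError(VntrStatError):
    """A packaged data fixture failed its integrity check."""
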