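"""Exception hierarchy for scoremr.

Every error raised on a violated precondition derives from :class:`ScoremrError`
so callers can catch analysis failures without swallowing programming errors.
"""


class ScoremrError(Exception):
    """Base class for all scoremr-specific errors."""


class ConfigurationError(ScoremrError, ValueError):
    """Invalid user-supplied configuration (ranges, weights, rep counts...)."""


class ModelError(ScoremrError, ValueError):
    """Structural model cannot be simulated (e.g. non-invertible reduced form)."""


class ScoreUndefinedError(ScoremrError):
    """An allele score cannot be formed for a cohort (constituent SNPs missing)."""


class InsufficientStudiesError(ScoremrError):
    """Fewer studies than a meta-analytic operation requires."""


class SingularDesignError(ScoremrError):
    """Rank-deficient regression design; carries the collinear column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class NoContrastError(ScoremrError):
    """Meta-regression covariate is constant across studies."""


class UndefinedRatioError(ScoremrError):
    """IV ratio undefined because the denominator association is exactly zero."""


class UndefinedR2Error(ScoremrError):
    """Variance explained undefined (zero-variance score)."""


class PipelineStageError(ScoremrError):
    """A pipeline stage failed; carries stage name and cohort context."""

    def __init__(self, stage, cohort=None, message=""):
        self.stage = stage
        self.cohort = cohort
        ctx = f" (cohort: {cohort})" if cohort else ""
        super().__init__(f"stage '{stage}' failed{ctx}: {message}")
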