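"""Exception types shared across the package."""


class AerolusError(Exception):
    """Base class for package-specific failures."""


class DomainError(AerolusError, ValueError):
    """An argument lies outside the domain an operation is defined on."""


class ConfigurationError(AerolusError, ValueError):
    """Inconsistent or incomplete configuration (e.g. no ROI at a required depth)."""


class UndefinedStatisticError(AerolusError, ArithmeticError):
    """A statistic is undefined on this input (e.g. CoV of a zero-mean block)."""


class SingularDesignError(AerolusError, ValueError):
    """Regression design matrix is rank deficient (e.g. constant covariate)."""


class UnresolvedConsensusError(AerolusError, ValueError):
    """Two raters disagree and no tiebreaking rater is available."""
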