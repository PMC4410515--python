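"""Exception types shared across the package."""


class ExplanationismError(ValueError):
    """Base class for domain errors."""


class DegenerateMarginalError(ExplanationismError):
    """Pr(E) lies outside (0, 1) where a measure needs a proper marginal."""


class UndefinedScoreError(ExplanationismError):
    """A measure's value is undefined for the given inputs (e.g. 0/0)."""


class ZeroProbabilityEvidenceError(ExplanationismError):
    """Updating on evidence with prior probability zero."""


class InvalidBonusError(ExplanationismError):
    """An explanatory bonus produced a negative update numerator."""


class NestingError(ExplanationismError):
    """A likelihood-ratio test was requested for non-nested models."""


class CollinearityError(ExplanationismError):
    """The regression design matrix is rank deficient."""


class DegenerateFitError(ExplanationismError):
    """A regression fit has zero residual variance (log-likelihood undefined)."""
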