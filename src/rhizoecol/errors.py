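"""Exception hierarchy shared across the package."""


class RhizoecolError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RhizoecolError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(RhizoecolError, ValueError):
    """An input table/vector violates a precondition (e.g. zero totals)."""


class EmptyResultError(RhizoecolError, ValueError):
    """An operation would return an empty result (e.g. rarefaction depth above every sample)."""


class UndefinedPairError(RhizoecolError, ValueError):
    """A pairwise quantity is undefined for at least one sample pair."""


class UndefinedRatioError(RhizoecolError, ZeroDivisionError):
    """A ratio has a zero denominator (e.g. zero fungal richness)."""


class LabelMismatchError(RhizoecolError, ValueError):
    """Two labelled matrices do not share the same labels/order."""


class MissingLeafError(RhizoecolError, KeyError):
    """Taxa in the table are absent from the phylogeny."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"{len(self.missing)} taxa missing from tree: {self.missing[:10]}")


class DegenerateNullError(RhizoecolError, ArithmeticError):
    """A null distribution has zero spread, so a standardized effect size is undefined."""


class DegeneratePredictorError(RhizoecolError, ValueError):
    """A regression predictor is constant."""


class UnfittableModelError(RhizoecolError, ValueError):
    """The model has no informative observations to fit."""


class InsufficientTaxaError(RhizoecolError, ValueError):
    """Too few taxa for the requested estimator (e.g. SparCC needs >= 4)."""


class UndefinedVulnerabilityError(RhizoecolError, ArithmeticError):
    """Network efficiency is zero, so relative efficiency loss is undefined."""


class NumericalFailureError(RhizoecolError, ArithmeticError):
    """An iterative algorithm produced non-finite values."""
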