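"""Exception hierarchy for the exposure pipeline."""


class FoodExposureError(Exception):
    """Base class for all package errors."""


class SnapError(FoodExposureError):
    """A point lies farther from the street network than the snapping tolerance."""


class DisconnectedError(FoodExposureError):
    """The origin's network component contains no reachable edges."""


class NoPathError(FoodExposureError):
    """Origin and destination lie in different network components."""


class UnknownModeError(FoodExposureError):
    """Transport mode outside the supported enumeration."""


class UnknownLabelError(FoodExposureError):
    """Raw outlet label missing from the taxonomy map."""


class RatioError(FoodExposureError):
    """Relative-density numerator exceeds its denominator."""


class DegenerateDistributionError(FoodExposureError):
    """A tertile class would be empty after tie handling."""


class EmptyCellError(FoodExposureError):
    """A raking margin category with positive target has no sample members."""


class NonConvergenceError(FoodExposureError):
    """Iterative fit did not reach tolerance within the iteration budget."""

    def __init__(self, message: str, max_margin_error: float | None = None):
        super().__init__(message)
        self.max_margin_error = max_margin_error


class ConvergenceError(FoodExposureError):
    """Maximum-likelihood fit failed to converge."""


class SeparationError(FoodExposureError):
    """Perfect prediction: the likelihood has no finite maximizer."""


class RankDeficiencyError(FoodExposureError):
    """Design matrix is rank deficient."""


class SingularDesignError(FoodExposureError):
    """Design correlation matrix is singular (e.g. duplicated covariate)."""


class SeparationWarning(UserWarning):
    """An outcome x covariate cell is empty; a penalized fallback was used."""


class PipelineStageError(FoodExposureError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
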