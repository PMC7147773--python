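"""Exception types shared across the package."""


class SVSError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(SVSError, ValueError):
    """An argument violates a documented precondition."""


class ThresholdNotFoundError(SVSError):
    """The observer perceived no presented level (latent threshold above the range)."""


class DegenerateVarianceError(SVSError):
    """A paired test was requested on differences with zero variance."""


class InvalidTaskError(SVSError, ValueError):
    """A measure was requested for the wrong task (standing vs walking)."""


class InsufficientStepsError(SVSError):
    """Fewer foot contacts than required for a stride window."""


class SequenceError(SVSError):
    """Foot-contact sequence does not alternate sides."""


class InsufficientDistanceError(SVSError):
    """Chest excursion shorter than the gait-speed measurement distance."""


class TrialRejectedError(SVSError):
    """A trial failed validation (e.g. a marker gap too long to interpolate)."""


class DesignError(SVSError, ValueError):
    """The factorial design is rank deficient or otherwise unusable."""
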