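"""Exception hierarchy for the foamplug pipeline."""


class FoamPlugError(Exception):
    """Base class for all foamplug-specific errors."""


class InvalidParameterError(FoamPlugError, ValueError):
    """A numeric parameter is out of its physical domain (non-finite,
    non-positive rate, negative length, ...)."""


class NoPlugFormed(FoamPlugError):
    """The foam never formed a plug above the detection gate.

    Mirrors the experimental observation that some foams fail to form a
    stable plug capable of displacing the blood substitute (e.g. all foams
    in the 10 mm phantom at 25 degrees inclination). A replicate raising
    this is a valid experimental outcome, counted — not imputed — by the
    condition-level aggregation.
    """


class IncompleteDegradation(FoamPlugError):
    """The recording ends before the plug has started to recede, so no
    degradation rate can be fitted."""


class AllPlugsFailed(FoamPlugError):
    """Every replicate of a condition raised :class:`NoPlugFormed`."""


class CalibrationError(FoamPlugError):
    """No foam-free background frame is available for background
    subtraction."""


class PackingError(FoamPlugError):
    """Bubble discs could not be placed without overlap within the retry
    budget."""


class RenderBoundsError(FoamPlugError, ValueError):
    """A simulated plug is longer than the rendered tube."""


class NoBubblesDetected(FoamPlugError):
    """A size distribution was requested for an empty set of bubbles."""
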