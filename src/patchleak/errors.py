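"""Exception hierarchy for the patchleak pipeline."""


class PatchLeakError(Exception):
    """Base class for all patchleak errors."""


class MalformedInputError(PatchLeakError):
    """A file or sample array violates the declared dialect or invariants."""


class StepNotFoundError(PatchLeakError, LookupError):
    """No voltage step matches the requested (voltage, occurrence)."""

    def __init__(self, voltage: float, occurrence: int):
        self.voltage = voltage
        self.occurrence = occurrence
        super().__init__(
            f"no step at {voltage:g} mV (occurrence {occurrence}) in this protocol"
        )


class AlignmentError(PatchLeakError):
    """Trace and protocol disagree in sampling interval or length."""


class DegeneratePairError(PatchLeakError):
    """The two leak-estimation steps have (effectively) identical voltages."""


class InsufficientDataError(PatchLeakError):
    """Too few samples remain in a fit window after blanking."""


class EmptyCurveError(PatchLeakError):
    """No usable I-V points (all fits excluded or out of range)."""


class DegenerateNormalizationError(PatchLeakError):
    """The leak line is flat over the voltage range; normalization undefined."""


class AggregationError(PatchLeakError):
    """Cohort curves do not share a common step-voltage set."""


class ParameterError(PatchLeakError, ValueError):
    """Invalid simulation or configuration parameter."""
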