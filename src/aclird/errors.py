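"""Exception hierarchy for the cutting-biomechanics pipeline."""


class AclIrdError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(AclIrdError):
    """A trial file does not conform to the documented column schema."""


class FormatError(AclIrdError):
    """A trial file is structurally readable but violates a format rule
    (e.g. non-uniform time step)."""


class ParameterError(AclIrdError):
    """An operation received an invalid argument."""


class EventDetectionError(AclIrdError):
    """Foot-contact / gait-event detection failed."""


class InsufficientStepsError(AclIrdError):
    """Too few segmented steps for the candidate-angle operator."""


class EligibilityError(AclIrdError):
    """A cut-angle eligibility filter could not be evaluated."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(message or f"eligibility filter failed at stage {stage!r}")


class NoCutDetectedError(AclIrdError):
    """All candidate cut angles were eliminated; carries the emptying stage."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(message or f"no cut detected (empty after stage {stage!r})")


class InsufficientDataError(AclIrdError):
    """Not enough observations/trials to compute the requested quantity."""


class UndefinedAsymmetryError(AclIrdError):
    """Asymmetry percentage is undefined (both limb summaries are zero)."""


class ReportError(AclIrdError):
    """Player report could not be assembled."""
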