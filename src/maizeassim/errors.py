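"""Exception hierarchy for the assimilation pipeline."""


class MaizeAssimError(Exception):
    """Base class for package errors."""


class ValidationError(MaizeAssimError):
    """Input data violates a schema or physical invariant."""


class InsufficientDataError(MaizeAssimError):
    """Too few usable samples for an estimation step."""


class FitError(MaizeAssimError):
    """Curve fit failed to converge after restarts."""


class SimulationError(MaizeAssimError):
    """The daily simulator could not complete a season."""
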