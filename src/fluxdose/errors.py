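"""Exception hierarchy for fluxdose."""


class FluxdoseError(Exception):
    """Base class for all fluxdose errors."""


class FormatError(FluxdoseError):
    """A model or catalog file failed to parse; message names the record."""


class ValidationError(FluxdoseError):
    """An object violated one of its invariants."""


class SolverError(FluxdoseError):
    """An LP/QP/MILP backend failed; carries the solver status message."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


class InfeasibleTreatmentError(SolverError):
    """No drug combination achieves the requested modulation target."""
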