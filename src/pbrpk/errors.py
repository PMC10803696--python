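"""Exception hierarchy for pbrpk."""


class PBRPKError(Exception):
    """Base class for all pbrpk errors."""


class ValidationError(PBRPKError):
    """A value violates a structural invariant (non-positive volume, negative rate, ...)."""


class DuplicateError(ValidationError):
    """An id collides with one already registered."""


class ReferentialError(ValidationError):
    """A reference (species, compartment, reaction) does not resolve."""


class SolverError(PBRPKError):
    """The ODE integrator failed or produced an inadmissible state."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class UnsupportedSBMLError(PBRPKError):
    """The SBML document uses a construct outside the supported core subset."""

    def __init__(self, construct: str):
        super().__init__(f"unsupported SBML construct: {construct}")
        self.construct = construct
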