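"""Exception hierarchy for model definition, evaluation and simulation."""


class CcmkinError(Exception):
    """Base class for all package errors."""


class ModelDefinitionError(CcmkinError):
    """A model table is inconsistent: unresolved symbol, duplicate name,
    missing parameter, bad stoichiometry."""


class DomainError(CcmkinError):
    """An input violates a documented precondition (e.g. negative
    concentration passed to an evaluation routine)."""


class EvaluationError(CcmkinError):
    """A rate law or ancillary rule produced a non-finite value; the message
    names the offending reaction or rule."""


class ContractError(CcmkinError):
    """A named quantity required by an operation is missing from its input
    (e.g. a flux named in the ATP balance is absent from the flux vector)."""


class IntegrationError(CcmkinError):
    """The ODE integrator failed; carries the last good time reached."""

    def __init__(self, message, t_last=None, worst_components=None):
        super().__init__(message)
        self.t_last = t_last
        self.worst_components = worst_components or []


class ConvergenceError(CcmkinError):
    """Steady-state search did not reach the requested residual tolerance."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual
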