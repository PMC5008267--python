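"""Exception hierarchy for trophodyn."""


class FoodWebError(Exception):
    """Base class for all trophodyn errors."""


class FormatError(FoodWebError):
    """A table or file does not have the expected layout."""


class ValidationError(FoodWebError):
    """A network violates a structural invariant; the message names node and rule."""


class BalanceError(FoodWebError):
    """Mass balancing failed (non-convergence or structural infeasibility)."""


class ParameterError(FoodWebError):
    """Rate constants cannot be derived from the energy budget."""


class IntegrationError(FoodWebError):
    """The ODE integrator failed; carries time and state snapshot in the message."""
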