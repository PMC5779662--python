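"""Exception hierarchy for model input validation and analysis failures."""


class HivCeaError(Exception):
    """Base class for all package errors."""


class ParameterValidationError(HivCeaError):
    """A model input violates one of its invariants."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(ParameterValidationError):
    """The parameter document does not match the documented schema."""


class NonStochasticRowError(ParameterValidationError):
    """A transition-matrix row does not sum to one (or has entries outside [0, 1])."""


class OutOfRangeError(ParameterValidationError):
    """A scalar input lies outside its admissible range."""


class InfeasibleAdjustmentError(HivCeaError):
    """A relative-risk or perturbation adjustment cannot keep a row stochastic."""


class DistributionFitError(HivCeaError):
    """A method-of-moments fit for a sampling distribution is infeasible."""

    def __init__(self, parameter: str, message: str):
        self.parameter = parameter
        super().__init__(f"{parameter}: {message}")
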