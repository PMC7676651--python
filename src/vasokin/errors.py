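"""Exception types raised across the package."""


class VasokinError(Exception):
    """Base class for package errors."""


class ConfigurationError(VasokinError):
    """A scenario or run configuration field is invalid."""


class ValidationError(VasokinError):
    """A tabular input violates the schema (named row/field in message)."""


class DegenerateDataError(VasokinError):
    """Input data admit no meaningful statistic (e.g. all-zero differences)."""


class InfeasibleMatchError(VasokinError):
    """No k-pair matching satisfies the caliper constraint."""

    def __init__(self, requested_k: int, max_feasible_k: int):
        self.requested_k = requested_k
        self.max_feasible_k = max_feasible_k
        super().__init__(
            f"no {requested_k}-pair matching satisfies the caliper; "
            f"largest feasible k is {max_feasible_k}"
        )
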