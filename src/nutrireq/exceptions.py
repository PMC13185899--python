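"""Exception hierarchy shared across the package."""


class NutrireqError(Exception):
    """Base class for all package errors."""


class SchemaError(NutrireqError):
    """A CSV header does not match the documented schema."""


class ValidationError(NutrireqError):
    """An input value violates a documented invariant."""


class DegenerateDesignError(NutrireqError):
    """The design matrix is singular (e.g. constant predictor)."""


class SampleSizeError(NutrireqError):
    """Too few observations for the requested operation."""


class NonConvergenceError(NutrireqError):
    """Every optimizer restart failed to converge.

    Carries the per-restart objective traces for diagnosis.
    """

    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces or []


class InferenceError(NutrireqError):
    """Bootstrap inference could not be completed (too many failed replicates)."""


class OracleError(NutrireqError):
    """The numeric root-finding oracle could not bracket a solution."""
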