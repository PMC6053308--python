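"""Exception types shared across the package."""


class TsmodError(Exception):
    """Base class for all package errors."""


class ParameterError(TsmodError, ValueError):
    """A physical parameter is outside its valid range."""


class InvalidInputError(TsmodError, ValueError):
    """Input data violates a documented precondition."""


class InvalidStateError(TsmodError, RuntimeError):
    """An object is not in the state an operation requires (e.g. unset LP)."""


class FitError(TsmodError, RuntimeError):
    """A fit failed to converge or was ill-posed."""


class EstimationError(TsmodError, RuntimeError):
    """A correction-coefficient estimate could not be formed."""
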