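"""Exception hierarchy for sparsev1."""


class SparseV1Error(Exception):
    """Base class for all sparsev1 errors."""


class ConfigurationError(SparseV1Error, ValueError):
    """Invalid configuration value or violated precondition."""


class DegenerateInputError(SparseV1Error, ValueError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class StateError(SparseV1Error, RuntimeError):
    """Network state is inconsistent (shape mismatch, uninitialized, ...)."""


class ContractError(SparseV1Error, RuntimeError):
    """A plasticity rule was applied to a weight group it does not govern."""


class NumericalInstabilityError(SparseV1Error, FloatingPointError):
    """Non-finite values appeared during simulation."""
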