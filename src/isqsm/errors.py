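"""Typed exceptions shared across the package."""


class IsqsmError(Exception):
    """Base class for all package errors."""


class ValidationError(IsqsmError, ValueError):
    """Invalid parameter or malformed domain object."""


class GridMismatchError(IsqsmError, ValueError):
    """Two volumes that must share a grid do not."""


class ConfigurationError(IsqsmError, ValueError):
    """A solver configuration that cannot produce a reconstruction."""


class NumericalError(IsqsmError, ArithmeticError):
    """Divergence or non-finite values during iteration."""


class ContractError(IsqsmError, AssertionError):
    """A caller-supplied operator pair violates its contract (e.g. adjointness)."""


class VolumeIOError(IsqsmError, OSError):
    """Problems reading or writing volume files."""
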