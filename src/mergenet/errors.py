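"""Shared exception hierarchy."""


class MergenetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MergenetError, ValueError):
    """A kinetic or structural parameter violates its invariant."""


class InvalidStateError(MergenetError, ValueError):
    """A species state vector violates non-negativity or shape constraints."""


class DomainError(MergenetError, ValueError):
    """An operation was evaluated outside its mathematical domain."""


class ConvergenceError(MergenetError, RuntimeError):
    """A steady-state solve or fit failed to converge."""


class DegenerateDesignError(MergenetError, ValueError):
    """The data table cannot identify the requested parameters."""


class DialectError(MergenetError, ValueError):
    """A file does not conform to the package CSV/config dialect."""
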