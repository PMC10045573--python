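"""Error taxonomy shared by all modules."""


class CootsegError(Exception):
    """Base class for all package errors."""


class DomainError(CootsegError, ValueError):
    """Input is syntactically valid but outside an operation's domain."""


class ShapeError(DomainError):
    """Congruence violation between grids that must share a shape."""


class FormatError(CootsegError, ValueError):
    """A file could not be parsed in its declared standard."""


class ArgumentError(CootsegError, ValueError):
    """An argument value is not among the accepted choices."""


class ConstraintError(DomainError):
    """A labeling violates a hard click constraint."""


class StateError(CootsegError, RuntimeError):
    """An operation was called on an object in the wrong state (e.g. untrained model)."""
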