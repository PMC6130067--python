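"""Exception hierarchy.

``DomainError`` doubles as :class:`ValueError` and ``ConvergenceError`` as
:class:`RuntimeError` so callers may catch either the package-specific or the
builtin class.
"""


class AcidBaseError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(AcidBaseError, ValueError):
    """An input lies outside the physically / mathematically admissible domain."""


class ConvergenceError(AcidBaseError, RuntimeError):
    """A root search failed to bracket or converge; the message names the inputs."""
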