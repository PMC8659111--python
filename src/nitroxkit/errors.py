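"""Exception hierarchy.

Every error raised on bad user input derives from :class:`InputError`
(itself a ``ValueError``) so callers and the CLI can distinguish usage
problems from genuine numerical failures.
"""


class NitroxkitError(Exception):
    """Base class for all package errors."""


class InputError(NitroxkitError, ValueError):
    """Invalid argument values, indices, units or missing fields."""


class DegenerateGeometryError(NitroxkitError):
    """Geometry does not define the requested frame (e.g. collinear C1, N, C2)."""


class NotADoubleWellError(NitroxkitError):
    """A scan expected to show two wells and an interior barrier does not."""


class UnsupportedRingError(InputError):
    """Puckering coordinates requested for a ring size outside {5, 6}."""


class ConvergenceError(NitroxkitError):
    """Iterative refinement failed to converge within its budget."""
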