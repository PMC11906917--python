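"""Exception hierarchy shared across the package.

Two failure families are distinguished so the CLI can map them to distinct
exit codes: malformed/invalid *input* versus a *geometric* degeneracy
encountered while computing (collinear fiducials, rays that cannot be cast,
non-convergent refinement, ...).
"""


class AnatLayoutError(Exception):
    """Base class for all package-specific errors."""


class InputError(AnatLayoutError, ValueError):
    """Raised for malformed, inconsistent, or out-of-contract inputs."""


class GeometryError(AnatLayoutError, RuntimeError):
    """Raised when a geometric construction is degenerate or fails."""
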