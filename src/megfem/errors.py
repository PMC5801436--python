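"""Exception types raised across the package."""


class MegfemError(Exception):
    """Base class for all package-specific errors."""


class InvalidResolutionError(MegfemError, ValueError):
    """Voxel resolution incompatible with the requested geometry."""


class SolverError(MegfemError, RuntimeError):
    """An iterative linear solve failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class RadialSourceError(MegfemError, ValueError):
    """The analytic magnetic field vanishes (radial source in a sphere);
    relative error metrics are undefined."""


class NumericalDegeneracyError(MegfemError, ValueError):
    """A closed-form expression is evaluated at a degenerate configuration
    (e.g. sensor on the dipole ray where the Sarvas denominator vanishes)."""
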