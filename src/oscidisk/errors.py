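"""Exception types shared across the package."""


class OscidiskError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OscidiskError, ValueError):
    """A simulation configuration violates a model invariant."""


class DegenerateGeometryError(OscidiskError, ValueError):
    """Coincident centers or a particle center exactly on a wall line."""


class IntegrationBlowUpError(OscidiskError, RuntimeError):
    """A particle acquired a non-finite coordinate or velocity."""

    def __init__(self, particle: int, time: float):
        self.particle = int(particle)
        self.time = float(time)
        super().__init__(
            f"integration blow-up: non-finite state for particle "
            f"{self.particle} at t={self.time:g}"
        )


class InitializationDensityError(OscidiskError, RuntimeError):
    """Rejection sampling could not place all particles."""


class InsufficientDataError(OscidiskError, ValueError):
    """An estimator was asked to run on too few samples."""


class DegenerateSampleError(OscidiskError, ValueError):
    """All samples identical; a power-law tail cannot be fitted."""


class ScenarioError(OscidiskError, KeyError):
    """Unknown fixture scenario name."""
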