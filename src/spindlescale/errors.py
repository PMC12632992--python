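"""Exception hierarchy shared across the package."""


class SpindleError(Exception):
    """Base class for all package-specific failures."""


class StabilityError(SpindleError):
    """Explicit time step violates the motor-field stability bound."""


class SimulationError(SpindleError):
    """Simulation entered an unphysical configuration (pole escape, coincident poles)."""


class InferenceError(SpindleError):
    """Catastrophe-rate inference could not produce a finite optimum."""


class FitError(SpindleError):
    """A least-squares trajectory fit failed to converge."""


class PeakDetectionError(SpindleError):
    """A kymograph frame does not contain the expected peaks."""


class OnsetNotFoundError(SpindleError):
    """No sustained chromosome-separation rise found in the series."""


class WindowError(SpindleError):
    """Too few samples inside a velocity-fit window."""


class GeometryError(SpindleError):
    """Degenerate spindle geometry (coincident plates, zero axis)."""


class SchemaError(SpindleError):
    """A data file does not conform to the documented schema."""
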