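"""Exception hierarchy used across the pipeline.

All errors raised by this package derive from :class:`ManimouseError`, so
callers can catch one type at a pipeline boundary while still discriminating
between configuration mistakes, malformed inputs, and detection failures.
"""


class ManimouseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ManimouseError, ValueError):
    """A parameter or configuration field is invalid (names the field)."""


class InputError(ManimouseError, ValueError):
    """Input data violates a precondition (shape, coverage, alphabet...)."""


class ParameterError(ManimouseError, ValueError):
    """A method parameter is incompatible with the data size."""


class DetectionError(ManimouseError, RuntimeError):
    """An image-analysis stage failed to find the expected structure."""


class DegenerateGeometryError(ManimouseError, ValueError):
    """A geometric fit is undefined (e.g. zero-variance point cloud)."""
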