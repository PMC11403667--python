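"""Exception hierarchy."""


class AzipartError(Exception):
    """Base class for all package errors."""


class ParameterError(AzipartError, ValueError):
    """Invalid or incomplete parameters."""


class IntegrationError(AzipartError, RuntimeError):
    """Langevin step too large for the grid; advises a smaller dt."""


class RangeError(AzipartError, ValueError):
    """A coordinate fell outside the supported grid range."""


class GridError(AzipartError, ValueError):
    """Grids mismatch or are not symmetric where symmetry is required."""


class StateError(AzipartError, RuntimeError):
    """Operation requested on an object in an invalid state (e.g. empty bias)."""


class FormatError(AzipartError, ValueError):
    """Malformed COLVAR/HILLS/PMF text file."""


class GeometryError(AzipartError, ValueError):
    """Solute geometry bound violated (head-tail span exceeds max length)."""


class EmptyDensityError(AzipartError, ValueError):
    """No samples fell inside the requested histogram range."""
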