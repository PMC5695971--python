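"""Exception hierarchy for qpatmi.

All package errors derive from :class:`QpatmiError` so callers (and the CLI)
can distinguish configuration, solver and convergence failures.
"""


class QpatmiError(Exception):
    """Base class for all qpatmi errors."""


class ConfigError(QpatmiError, ValueError):
    """Invalid configuration or input contract violation."""


class ShapeError(ConfigError):
    """Mismatched array shapes or incompatible grids/wavelength lists."""


class DegenerateDistributionError(QpatmiError, ValueError):
    """A chromophore map is constant: its density, entropy and MI are undefined."""


class InvalidBandwidthError(ConfigError):
    """Kernel bandwidth must be strictly positive."""


class GridCoverageError(ConfigError):
    """Evaluation grid does not cover the sample range."""


class WavelengthRangeError(ConfigError):
    """Requested wavelength lies outside the spectral library band."""


class GeometryError(ConfigError):
    """Phantom insertions overlap or fall outside the domain."""


class DiffusionValidityError(ConfigError):
    """Non-positive reduced scattering: diffusion approximation invalid."""


class SolverFailureError(QpatmiError, RuntimeError):
    """The discretized diffusion system could not be solved."""


class AlignmentError(ShapeError):
    """Pressure stacks do not share grid or wavelength list."""


class CalibrationError(QpatmiError, ValueError):
    """Calibration factor is undefined (zero model stack)."""


class CorrectionError(QpatmiError, ValueError):
    """Non-positive divisor in calibration/Grueneisen pre-correction."""


class MetricError(ConfigError):
    """Empty ROI mask or invalid error-metric specification."""
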