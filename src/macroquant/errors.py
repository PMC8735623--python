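"""Exception hierarchy.

Everything raised deliberately by macroquant derives from
:class:`MacroquantError`, so callers (and the CLI) can distinguish
validation failures from genuine bugs.
"""


class MacroquantError(Exception):
    """Base class for all macroquant errors."""


class ConfigError(MacroquantError, ValueError):
    """Invalid configuration or simulation parameters."""


class ParseError(MacroquantError, ValueError):
    """Malformed input file (missing columns, bad values, bad spacing)."""


class WindowFitError(MacroquantError, ValueError):
    """Analysis windows do not fit inside the profile or image."""


class CalibrationError(MacroquantError, ValueError):
    """Requested calibration target is unreachable."""


class GaussianFitError(MacroquantError, RuntimeError):
    """Gaussian peak fit failed to converge or produced a degenerate fit."""


class NonPositiveCytoplasmError(MacroquantError, ValueError):
    """Background-corrected cytoplasmic mean is non-positive; the profile
    cannot yield a meaningful membrane/cytoplasm ratio and is excluded."""
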