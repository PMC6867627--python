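"""Exception hierarchy shared across the package.

Grouped into input/format problems, configuration problems, and
estimation/fit problems so the CLI can map them onto distinct exit codes.
"""


class RinglaneError(Exception):
    """Base class for all package-specific errors."""


class InputError(RinglaneError):
    """Malformed or inconsistent input data (files, arrays, masks)."""


class FormatError(InputError):
    """A table is missing required columns or cannot be parsed."""


class SamplingError(InputError):
    """A trajectory violates the uniform-sampling contract."""


class ProjectionError(InputError):
    """A tracking point cannot be projected onto the ring (e.g. at the center)."""


class UnwrapError(InputError):
    """Angle unwrapping is ambiguous (a step of magnitude exactly pi)."""


class ConfigurationError(RinglaneError):
    """Invalid parameter values in a config object."""


class EstimationError(RinglaneError):
    """An estimator cannot produce a value (empty sample, degenerate variance...)."""


class FitError(EstimationError):
    """The dwell-time survival fit has too few usable points."""


class DegenerateFitError(FitError):
    """The log-survival slope is non-negative, so tau is undefined."""
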