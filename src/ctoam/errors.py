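"""Exception hierarchy for the CTOAM pipeline.

Every stage raises a subclass of :class:`CtoamError` so callers can trap
pipeline failures without catching unrelated exceptions.
"""


class CtoamError(Exception):
    """Base class for all pipeline errors."""


class SpecError(CtoamError):
    """A synthetic-volume or run specification is internally inconsistent."""


class GeometryError(CtoamError):
    """Geometry (ridge, view axis, ...) is degenerate or out of bounds."""


class CohortError(CtoamError):
    """A cohort request cannot yield valid paired statistics (e.g. n < 2)."""


class InputError(CtoamError):
    """An input array/region is empty or malformed."""


class DegenerateFitError(CtoamError):
    """Calibration regression is degenerate (identical insert HU, zero slope)."""


class ProjectionError(CtoamError):
    """Maximum intensity projection cannot be formed (e.g. empty mask)."""


class ConfigError(CtoamError):
    """A numeric configuration value is outside its documented range."""


class FrameError(CtoamError):
    """A point falls outside the grid frame it is being mapped into."""


class PairingError(CtoamError):
    """Longitudinal pairing is incomplete; message lists offending subjects."""


class ConsistencyError(CtoamError):
    """Inputs that must share provenance (subject/view/timepoint) do not."""
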