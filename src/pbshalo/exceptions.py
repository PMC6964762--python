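"""Exception hierarchy for pbshalo.

All errors derive from :class:`PbsHaloError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
mirror the distinct failure modes of the pipeline stages.
"""


class PbsHaloError(Exception):
    """Base class for all pbshalo errors."""


class InvalidParameterError(PbsHaloError, ValueError):
    """A parameter violates its documented constraint (e.g. sigma <= 0)."""


class DomainError(PbsHaloError, ValueError):
    """An input is structurally valid but outside the supported domain
    (e.g. a grid too small to contain the spot halo)."""


class RegistrationError(PbsHaloError, RuntimeError):
    """Exposure registration failed: no overlapping trusted region."""


class NoPeakError(PbsHaloError, ValueError):
    """An image has no usable intensity peak (flat or empty)."""


class EmptyProfileError(PbsHaloError, ValueError):
    """Radial averaging selected no pixels (bad mask or interval)."""


class OutOfRangeError(PbsHaloError, ValueError):
    """A profile never crosses the requested intensity level
    (the measurement grid is too small for the requested width)."""


class AlignmentError(PbsHaloError, ValueError):
    """Two tables to be compared do not cover the same index set."""


class FormatError(PbsHaloError, ValueError):
    """A file is missing required metadata or is malformed."""
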