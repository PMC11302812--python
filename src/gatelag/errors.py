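"""Exception and warning hierarchy for gatelag."""


class GatelagError(Exception):
    """Base class for all gatelag errors."""


class InvalidInputError(GatelagError, ValueError):
    """Inputs violate a precondition (wrong shape, too few samples, bad sign)."""


class DegenerateFitError(GatelagError):
    """A regression cannot be computed (e.g. zero time variance)."""


class GeometryError(GatelagError):
    """A rendered or requested footprint does not fit inside the image."""


class NoBallFoundError(GatelagError):
    """No attenuation region rises above the detection threshold."""


class AmbiguousDetectionError(GatelagError):
    """More than one disjoint region exceeds the detection threshold."""


class SearchRangeError(GatelagError):
    """The beam-off matching objective has no minimum inside the search range."""


class ConfigError(GatelagError):
    """A configuration file is missing, malformed, or contains unknown keys."""


class QualityWarning(UserWarning):
    """A measurement succeeded but a sanity diagnostic disagrees."""


class DegenerateTraceWarning(UserWarning):
    """A blur trace is too short to show a clear plateau; edges are best-effort."""
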