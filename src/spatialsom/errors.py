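"""Exception hierarchy for spatialsom."""


class SpatialSOMError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(SpatialSOMError, ValueError):
    """Malformed input file or violated container invariant (duplicate ids, bad shape)."""


class ParseError(SpatialSOMError, ValueError):
    """Unparseable cell or line; message carries the offending coordinates."""


class StateError(SpatialSOMError, RuntimeError):
    """Operation applied to an object in the wrong state (e.g. double log-transform)."""


class DesignError(SpatialSOMError, ValueError):
    """Inconsistent synthetic-embryo design."""


class EvaluationError(SpatialSOMError, ValueError):
    """Reconstruction cannot be scored (e.g. an empty spatial domain)."""
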