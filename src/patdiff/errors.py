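"""Exception hierarchy used across the toolkit."""


class PatdiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PatdiffError):
    """Invalid user-supplied configuration (ranges, fractions, filter bands, ...)."""


class GeometryError(PatdiffError):
    """Image / detector-ring geometry mismatch (e.g. phantom outside the ring)."""


class ReconstructionError(PatdiffError):
    """Back-projection failure, e.g. an arrival time outside the recorded window."""


class DataError(PatdiffError):
    """Shape or content mismatch in training/evaluation data."""


class DivergenceError(PatdiffError):
    """Non-finite state encountered during reverse-time sampling."""
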