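"""Exception hierarchy.

Every error raised on a defined failure path of the analysis chain derives
from :class:`ThylakoidBiophysError`, so callers (and the CLI) can separate
scientific "no signal" outcomes from programming errors.
"""


class ThylakoidBiophysError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(ThylakoidBiophysError):
    """Light/flash protocol events overlap, are out of order or out of range."""


class NoOpenEventsError(ThylakoidBiophysError):
    """Amplitude histogram is unimodal: no resolvable channel openings."""


class InsufficientDataError(ThylakoidBiophysError):
    """Too few points for the requested fit (e.g. one point in a voltage branch)."""


class UnidentifiableError(ThylakoidBiophysError):
    """Requested inversion has no unique solution (e.g. symmetric salt for GHK)."""


class NoDecayError(ThylakoidBiophysError):
    """ECS dark-interval segment does not decay; no time constant can be fitted."""


class NoPmfSignalError(ThylakoidBiophysError):
    """Total ECS amplitude across the light-dark transition is not positive."""


class NoBraggPeakError(ThylakoidBiophysError):
    """Fitted Bragg-peak amplitude is consistent with zero."""


class TraceFormatError(ThylakoidBiophysError):
    """A trace/curve file violates the columnar format contract."""


class ConfigError(ThylakoidBiophysError):
    """Run configuration contains unknown keys or invalid values."""
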