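"""Exception hierarchy shared across the package."""


class PangemError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PangemError, ValueError):
    """A configuration object is internally contradictory or out of range."""


class GprParseError(PangemError, ValueError):
    """A gene-protein-reaction rule string is malformed."""


class ModelError(PangemError, ValueError):
    """A metabolic network violates a structural invariant."""


class TraceError(PangemError, ValueError):
    """A kinetic trace cannot be processed (too short, missing values)."""


class DegenerateControlsError(PangemError, ValueError):
    """Negative-control wells have zero spread; z-test undefined."""


class GapFillError(PangemError, RuntimeError):
    """No addition of universal reactions can restore the required growth."""
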