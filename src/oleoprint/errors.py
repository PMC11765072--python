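"""Exception hierarchy shared across the package."""


class OleoprintError(Exception):
    """Base class for all package-specific errors."""


class MalformedSweepError(OleoprintError, ValueError):
    """A temperature sweep violates its invariants (ordering, positivity, size)."""


class NoCrossingError(OleoprintError, ValueError):
    """G' - G'' keeps one sign over the whole sweep: the sample never crosses
    tan(delta) = 1 in the measured range (never gels, or never melts)."""


class DomainError(OleoprintError, ValueError):
    """A scalar argument lies outside its physical domain (e.g. modulus <= 0)."""


class OutOfRangeError(OleoprintError, ValueError):
    """An interpolation query lies outside the measured grid and extrapolation
    was not enabled."""


class StabilityError(OleoprintError, RuntimeError):
    """The explicit time step violates the FTCS stability bound."""


class SchemaError(OleoprintError, ValueError):
    """An input file does not conform to the canonical CSV/YAML schema."""


class ConfigError(OleoprintError, ValueError):
    """A run or simulation configuration is incomplete or inconsistent."""
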