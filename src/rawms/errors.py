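"""Exception hierarchy for the rawms pipeline."""


class RawMsError(Exception):
    """Base class for all rawms errors."""


class FormatError(RawMsError):
    """A file does not parse as the named standard."""


class ValidationError(RawMsError):
    """An in-memory object violates a structural invariant."""


class SchemeMismatchError(ValidationError):
    """Isolation-window schemes differ across runs."""


class RangeError(ValidationError):
    """A coordinate falls outside the configured axis range."""


class DegenerateRunError(ValidationError):
    """A scan series has no retention-time extent."""


class AssemblyError(ValidationError):
    """Per-sample feature concatenation is missing an input vector."""


class EmptyMatrixError(ValidationError):
    """Feature filtering removed every column."""


class SplitError(ValidationError):
    """A stratified split cannot be formed."""


class CVError(ValidationError):
    """Cross-validation cannot be run with the requested fold count."""


class EncoderError(RawMsError):
    """An encoder failed or its declared contract does not hold."""


class OptionalDependencyError(EncoderError):
    """An external-encoder backend is not installed."""


class DegenerateTestError(RawMsError):
    """A statistical test is undefined on the given input."""


class ConfigError(RawMsError):
    """A synthetic-cohort or sweep configuration is inconsistent."""
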