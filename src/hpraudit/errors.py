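"""Exception hierarchy for the HPR engine.

All engine-raised exceptions derive from :class:`HPRError` so callers (and
the CLI) can map error categories to exit codes without string matching.
"""


class HPRError(Exception):
    """Base class for all errors raised by this package."""


class ProtocolParseError(HPRError):
    """A protocol/audit/bands file could not be parsed; names the line."""


class ValidationError(HPRError):
    """Structural invariant violated (protocol, audit or band table)."""


class DomainError(HPRError):
    """Arithmetic input outside its allowed domain (score, weight, unit)."""


class ConfigurationError(HPRError):
    """A control point lacks the configuration its kind requires."""


class EmptyAuditError(HPRError):
    """No observed control point contributes a theoretical maximum."""
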