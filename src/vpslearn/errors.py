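"""Exception types shared across the package."""


class VpsLearnError(Exception):
    """Base class for all package errors."""


class CaseValidationError(VpsLearnError):
    """A case-definition file violates the case schema or its invariants."""


class LogValidationError(VpsLearnError):
    """An action-log file violates the log schema or its invariants."""


class ScoringError(VpsLearnError):
    """A metric cannot be computed for the given case/log combination."""
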