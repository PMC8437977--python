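"""Exception hierarchy shared across the package."""


class NtcpError(Exception):
    """Base class for all package errors."""


class MalformedInputError(NtcpError, ValueError):
    """An input file or array violates the format contract."""


class ConfigurationError(NtcpError, ValueError):
    """An option or configuration value is unknown or inconsistent."""


class ContractError(NtcpError, ValueError):
    """A caller violated an API precondition (missing feature, length mismatch)."""


class DomainError(NtcpError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DegenerateDataError(NtcpError, ValueError):
    """Data cannot support the requested estimate (single-class outcome, constant feature)."""


class SeparationError(NtcpError, RuntimeError):
    """Logistic MLE diverged because the outcome is perfectly separated."""


class GenerationError(NtcpError, RuntimeError):
    """A synthetic-data request is infeasible (e.g. dose scaling beyond the cap)."""
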