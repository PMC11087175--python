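"""Package-wide exception types."""


class DomainError(ValueError):
    """Input outside the physically supported domain."""


class AnalysisError(RuntimeError):
    """An analysis could not be completed on the given data."""


class ConfigurationError(ValueError):
    """Inconsistent or infeasible configuration."""
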