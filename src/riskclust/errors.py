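"""Exception taxonomy shared across the pipeline stages."""


class RiskclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RiskclustError):
    """A user-supplied configuration value is inconsistent or out of range."""


class InputError(RiskclustError):
    """Input data violate a stage precondition."""


class PipelineError(RiskclustError):
    """A stage produced an unusable intermediate (e.g. all columns pruned)."""


class AllocationError(RiskclustError):
    """Stratified sampling cannot honour the requested allocation."""


class OptimizationError(RiskclustError):
    """Numerical optimization diverged."""
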