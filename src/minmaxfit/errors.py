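"""Exception hierarchy shared across the package."""


class MinmaxFitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MinmaxFitError, ValueError):
    """Invalid parameters, malformed input files, or broken invariants."""


class SolverError(MinmaxFitError, RuntimeError):
    """A backend optimisation routine failed to return a usable solution."""


class InfeasibleError(ValidationError):
    """A tiered system admits no feasible path through all tiers."""
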