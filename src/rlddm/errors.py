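"""Exception hierarchy for the rlddm package."""


class RLDDMError(Exception):
    """Base class for all package errors."""


class SchemaError(RLDDMError):
    """A trial table is missing a required column or has an unusable dtype."""


class ValidationError(RLDDMError):
    """A trial table row violates a domain invariant (e.g. rt <= 0)."""


class EmptySessionError(RLDDMError):
    """An operation received a session with no usable trials."""


class DomainError(RLDDMError):
    """A numerical routine was called outside its valid domain."""


class ConvergenceError(RLDDMError):
    """MCMC diagnostics failed the configured convergence gate."""
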