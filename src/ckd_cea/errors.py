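"""Exception hierarchy shared across the package."""


class CkdCeaError(Exception):
    """Base class for all package-specific errors."""


class InvalidTrialError(CkdCeaError):
    """A trial record violates its invariants (n < 2, non-positive SD, ...)."""


class InsufficientStudiesError(CkdCeaError):
    """An operation requiring >= 2 studies received fewer."""


class DegenerateDesignError(CkdCeaError):
    """Meta-regression covariate is constant (or otherwise rank-deficient)."""


class ConfigError(CkdCeaError):
    """A parameter/config value is outside its admissible range."""


class ExcludedPatientError(CkdCeaError):
    """A simulated patient falls outside the modelled CKD stages at baseline."""


class UndefinedTransitionError(CkdCeaError):
    """Zero person-years at risk: the transition probability is undefined."""


class InfeasibleMatrixError(CkdCeaError):
    """Requested transition probabilities cannot form a valid stochastic row."""


class FixtureCorruptionError(CkdCeaError):
    """A packaged data fixture failed its checksum."""
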