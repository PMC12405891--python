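"""Exception hierarchy shared across the package."""


class EnBayesError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EnBayesError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(EnBayesError, ValueError):
    """A data file could not be parsed; the message names the offending line."""


class AlignmentError(EnBayesError, ValueError):
    """Genotype and phenotype line identifiers have an empty intersection."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested for a constant vector."""


class DegenerateObjectiveError(ValidationError):
    """An ensemble objective is undefined (e.g. constant ensemble prediction)."""


class SamplerError(EnBayesError, RuntimeError):
    """The MCMC chain reached a non-finite state; the message names the iteration."""


class OptimizationError(EnBayesError, RuntimeError):
    """The genetic algorithm could not make progress (e.g. all-degenerate fitness)."""


class NumericalError(EnBayesError, RuntimeError):
    """A linear system was singular or ill-conditioned."""
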