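"""Exception hierarchy shared across the package."""


class ParetoMetabError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(ParetoMetabError, ValueError):
    """A model file could not be parsed in the named format."""


class ModelValidationError(ParetoMetabError, ValueError):
    """A parsed network violates a structural invariant (e.g. lb > ub)."""


class ConfigurationError(ParetoMetabError, ValueError):
    """Required configuration (biomass/ATP reaction, exchange ids) missing."""


class FormulaError(ParetoMetabError, ValueError):
    """A chemical formula string could not be parsed."""


class GprLookupError(ParetoMetabError, KeyError):
    """A gene referenced by a GPR rule is missing from an activity map."""


class SolverError(ParetoMetabError, RuntimeError):
    """The LP/QP backend failed in an unexpected way."""


class InsufficientOverlapError(ParetoMetabError, ValueError):
    """Too few shared genes/metabolites between an omics profile and the model."""


class InsufficientDataError(ParetoMetabError, ValueError):
    """Not enough points/bins to carry out a surface projection."""


class EmptyParetoSetError(ParetoMetabError, RuntimeError):
    """Sampling produced no Pareto solutions at all."""
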