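"""Exception hierarchy shared across the package."""


class LiabheritError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(LiabheritError, ValueError):
    """A simulation or model configuration violates its invariants."""


class InvalidInputError(LiabheritError, ValueError):
    """Input data violate a precondition (shape, alignment, emptiness)."""


class PedigreeIntegrityError(LiabheritError, ValueError):
    """Cyclic parentage or an individual that is its own ancestor."""


class FormatError(LiabheritError, IOError):
    """A genotype/GRM/pedigree file does not conform to its layout."""


class ResourceBudgetError(LiabheritError, RuntimeError):
    """A rejection-sampling or iteration budget would be exceeded."""


class NumericalError(LiabheritError, RuntimeError):
    """A numerical routine failed to converge or produced non-finite values."""
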