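"""Exception types shared across the package."""


class LitvarError(Exception):
    """Base class for all package errors."""


class ValidationError(LitvarError, ValueError):
    """Invalid configuration or malformed input data."""


class CalibrationError(LitvarError, ValueError):
    """The requested trait moments and heritability are jointly infeasible."""


class PedigreeError(LitvarError, ValueError):
    """Cyclic, unordered or otherwise inconsistent pedigree."""


class SelectionError(LitvarError, ValueError):
    """Selection cannot be carried out on the given candidate pool."""


class ModelError(LitvarError, ValueError):
    """A model cannot be fitted on the given data (empty cells, rank deficiency...)."""
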