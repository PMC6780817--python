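"""Exception types shared across the analysis modules."""


class DrugComboError(ValueError):
    """Base class for analysis errors."""


class InvalidControlError(DrugComboError):
    """Vehicle-control absorbance does not exceed the media blank."""


class InsufficientDataError(DrugComboError):
    """Too few usable dose-effect points to fit the model."""


class DegenerateDesignError(DrugComboError):
    """Experimental design carries no usable contrast (e.g. a single dose,
    a checkerboard without single-agent margins, a dead control well)."""


class DomainError(DrugComboError):
    """Argument outside the mathematical domain of the operation."""


class LabelMismatchError(DrugComboError):
    """Drug labels of fits and the combination design do not agree."""
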