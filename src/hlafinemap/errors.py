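"""Exception hierarchy for hlafinemap."""


class HlaFinemapError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(HlaFinemapError):
    """A configuration value is outside its documented range."""


class InvalidInputError(HlaFinemapError):
    """Input data violates a precondition (shape, classes, content)."""


class MissingDataError(HlaFinemapError):
    """An individual/gene combination carries no usable posterior mass."""


class UnresolvableAlleleError(HlaFinemapError):
    """An allele referenced by a dosage matrix is absent from the alignment."""


class DegeneratePredictorError(HlaFinemapError):
    """A predictor is constant and cannot be tested."""


class SimulationError(HlaFinemapError):
    """The simulator could not satisfy its sampling quotas."""


class SearchBudgetError(HlaFinemapError):
    """An exhaustive search would exceed the configured model budget."""


class DependencyError(HlaFinemapError):
    """A pipeline stage was requested without a stage it depends on."""
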