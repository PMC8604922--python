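"""Exception hierarchy shared across the package."""


class SliceleakError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SliceleakError, ValueError):
    """Invalid configuration (shapes, regions, incompatible flags)."""


class InputError(SliceleakError, ValueError):
    """Invalid input data (empty sets, wrong shapes, non-finite values)."""


class DegenerateInputError(InputError):
    """Numerically degenerate input, e.g. zero variance where an SD divisor is needed."""


class ConsistencyError(SliceleakError, ValueError):
    """Cross-object inconsistency, e.g. a slice not covered by a fold assignment."""


class TrainingError(SliceleakError, RuntimeError):
    """Model training failure (non-finite loss), with fold/grid context when known."""


class UnavailableWeightsError(SliceleakError, RuntimeError):
    """A transfer-learning family was requested but no pretrained weights are present."""
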