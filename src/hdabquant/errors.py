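"""Exception hierarchy shared across the pipeline."""


class HdabQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HdabQuantError, ValueError):
    """A parameter violates its documented contract."""


class EstimationFailedError(HdabQuantError):
    """Stain-vector estimation could not find two stain populations.

    Callers are advised to fall back to :func:`default_hdab_vectors`.
    """


class InsufficientTrainingError(HdabQuantError):
    """The training set is missing at least one of the three classes."""

    def __init__(self, missing_classes):
        self.missing_classes = tuple(missing_classes)
        super().__init__(
            "training set is missing required class(es): "
            + ", ".join(self.missing_classes)
        )


class FeatureMismatchError(HdabQuantError):
    """Objects were measured with features the model does not know."""

    def __init__(self, missing_features):
        self.missing_features = tuple(missing_features)
        super().__init__(
            "objects are missing model features: " + ", ".join(self.missing_features)
        )


class MeasurementError(HdabQuantError):
    """A detection could not be measured (degenerate geometry)."""


class UndefinedRateError(HdabQuantError):
    """Positivity rate is undefined: no countable (positive+negative) cells."""


class GenerationError(HdabQuantError):
    """Synthetic-data generation failed (e.g. infeasible nucleus packing)."""


class DialectError(HdabQuantError):
    """A results file does not conform to the documented TSV dialect."""


class IntegrityError(HdabQuantError):
    """An inventory or join violates a uniqueness contract."""
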