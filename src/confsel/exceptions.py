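"""Named error types raised across the toolkit."""


class ConfselError(Exception):
    """Base class for all confsel errors."""


class DatasetFileError(ConfselError):
    """The dataset file is missing or unreadable."""


class MissingLabelColumnError(ConfselError):
    """The requested label column is absent from the table."""


class NonNumericFeatureError(ConfselError):
    """A descriptor cell is non-numeric or non-finite."""


class LabelDomainError(ConfselError):
    """A label value is outside {0, 1}."""


class EmptyDatasetError(ConfselError):
    """The table contains no data rows."""


class SplitError(ConfselError):
    """A train/test split request is infeasible (fraction or size)."""


class SingleClassError(ConfselError):
    """A fitting operation received training data with only one class."""


class DimensionMismatchError(ConfselError):
    """Query feature dimensionality differs from the fitted model's."""


class ResamplingError(ConfselError):
    """A resampling request is infeasible (too few points, bad counts)."""


class MetricError(ConfselError):
    """A metric was requested on degenerate inputs (empty, single-class)."""


class ConfigurationError(ConfselError):
    """A run configuration value is invalid or unknown."""
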