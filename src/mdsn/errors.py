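"""Exception hierarchy for the mdsn pipeline."""


class MdsnError(Exception):
    """Base class for all mdsn-specific errors."""


class IdentifierCollisionError(MdsnError):
    """Duplicate feature or sample identifiers in an input table."""


class ParseError(MdsnError):
    """A cell of an input table could not be parsed as a finite number."""


class DomainError(MdsnError):
    """An input value lies outside the operation's domain (e.g. negative abundance)."""


class AlreadyProcessedError(MdsnError):
    """preprocess_expression applied to a matrix that is already log/z-scored."""


class LabelError(MdsnError):
    """A stage label outside the configured ordered label set."""


class AlignmentError(MdsnError):
    """Sample intersection between matrices/annotations is empty."""


class GroupSizeError(MdsnError):
    """A sample group is too small for the Fisher variance term (needs n >= 4)."""


class ConstantVectorError(MdsnError):
    """Pearson correlation requested for a zero-variance vector."""


class DegenerateNetworkError(MdsnError):
    """Fewer than two miRNAs with any dysregulated target."""


class FitUndefinedError(MdsnError):
    """Scale-free fit has fewer than 3 non-empty histogram bins."""


class ThresholdSelectionError(MdsnError):
    """No grid threshold reaches the required scale-free fit score."""

    def __init__(self, message, best_threshold=None, best_score=None):
        super().__init__(message)
        self.best_threshold = best_threshold
        self.best_score = best_score


class CoverageError(MdsnError):
    """A partition does not cover every node of the graph."""


class ComparisonError(MdsnError):
    """Two partitions share no nodes; NMI undefined."""


class DegenerateLabelError(MdsnError):
    """Classifier fit requested with fewer than two classes present."""


class StratificationError(MdsnError):
    """A cross-validation fold is missing a class."""


class ParameterError(MdsnError):
    """Unreachable simulation parameter (e.g. |rho| >= 1)."""
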