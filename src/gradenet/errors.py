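"""Exception hierarchy for the gradenet pipeline.

Degenerate-data conditions that a run should survive (a constant expression
vector, an empty edge intersection) are *signals*: they are raised as their
own exception types so callers can catch them and skip the offending pair,
FFL or network rather than abort the whole analysis.
"""


class GradenetError(Exception):
    """Base class for all gradenet errors."""


class ConfigurationError(GradenetError):
    """A parameter is outside its documented range or a required input is missing."""


class ConsistencyError(GradenetError):
    """Inputs contradict each other (e.g. a planted edge absent from the prior)."""


class UndefinedCorrelationError(GradenetError):
    """Correlation is undefined (constant vector); the pair should be excluded."""


class UndefinedProfileError(GradenetError):
    """A triad significance profile cannot be formed (all-zero Z-scores or empty graph)."""


class ValidationFailedError(GradenetError):
    """Independent validation degenerated (e.g. k-means produced an empty cluster)."""
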