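"""Exception hierarchy shared across the package.

``DataError`` signals a problem with user-supplied data (missing file,
empty set after cleaning, malformed matrix) and maps to CLI exit code 2;
``UsageError``-type problems are handled by the CLI layer itself.
"""


class DruglikeError(Exception):
    """Base class for all package-specific errors."""


class DataError(DruglikeError):
    """Invalid, missing or degenerate input data."""


class TrainingError(DruglikeError):
    """Numerical failure during network training (e.g. non-finite loss)."""
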