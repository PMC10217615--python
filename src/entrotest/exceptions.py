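"""Exception hierarchy.

All input-validation failures derive from :class:`EntrotestError` so callers
can catch library errors without masking genuine bugs.
"""


class EntrotestError(ValueError):
    """Base class for all entrotest input errors."""


class InvalidInputError(EntrotestError):
    """Malformed counts, probabilities, partitions or file content."""


class InvalidOrderError(EntrotestError):
    """An entropy order q outside the family's admissible range."""


class DegenerateSupportError(EntrotestError):
    """Zero probabilities where a derivative or variance term diverges."""


class DegenerateTestError(EntrotestError):
    """A two-sample test whose combined asymptotic variance is zero."""
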