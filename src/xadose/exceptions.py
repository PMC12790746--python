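"""Exception hierarchy for the pipeline.

Exit-code mapping used by the CLI: InputError -> 2, NumericalError -> 3.
"""


class XadoseError(Exception):
    """Base class for all package errors."""


class InputError(XadoseError):
    """Invalid user input: malformed files, bad parameters, inconsistent tables."""


class FormatError(InputError):
    """A tabular file violates the expected layout (ragged rows, missing columns,
    duplicate labels, non-integer counts)."""


class ConsistencyError(InputError):
    """Cross-table validation failure (e.g. a sample present in the count matrix
    but absent from the sample sheet)."""


class ParameterError(InputError):
    """A numeric parameter is outside its admissible range."""


class NumericalError(XadoseError):
    """A numerical procedure failed (degenerate null, undefined ratio,
    non-convergence that cannot be flagged per-gene)."""
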