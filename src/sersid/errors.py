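"""Exception hierarchy shared across the package.

``ValidationError`` covers violated data-model invariants and bad
arguments; ``FormatError`` covers malformed input files; ``NumericalError``
covers linear-algebra failures (singular smoothing systems and the like).
The CLI maps these onto distinct exit codes.
"""


class ValidationError(ValueError):
    """A data invariant or argument precondition was violated."""


class FormatError(ValidationError):
    """An input file does not conform to the expected table layout."""


class NumericalError(RuntimeError):
    """A numerical procedure failed (e.g. a singular penalized system)."""
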