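"""Exception hierarchy shared across the package.

Exit codes (used by the CLI): 2 input error, 3 parameter error,
4 internal invariant violation.
"""


class PTBTError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PTBTError):
    """Malformed or inconsistent input data (trees, trait tables, files)."""

    exit_code = 2


class ParameterError(PTBTError):
    """A parameter outside its documented range."""

    exit_code = 3


class InvariantError(PTBTError):
    """An internal invariant was violated; indicates a bug, not bad input."""

    exit_code = 4
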