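"""Exception hierarchy shared across the package.

ValidationError signals bad user input (CLI exit code 2);
ComputationError signals a numerical failure such as non-convergence
(CLI exit code 3).
"""


class SynfoldError(Exception):
    """Base class for all package errors."""


class ValidationError(SynfoldError):
    """Invalid input: missing files, bad selections, malformed configs."""

    exit_code = 2


class ComputationError(SynfoldError):
    """A computation failed: non-convergence, degenerate geometry, etc."""

    exit_code = 3
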