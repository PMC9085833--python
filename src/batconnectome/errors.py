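"""Exception taxonomy shared across the pipeline.

Two classes matter to callers (and to the CLI's exit codes): problems with
user-supplied inputs or files (`InputError`, exit status 2) and violations of
an operation's contract detected at run time (`ContractError`, exit status 3).
"""


class InputError(ValueError):
    """A user-supplied value, file, or gene set is malformed or inadmissible."""


class FormatError(InputError):
    """A file does not conform to its declared dialect."""


class ContractError(RuntimeError):
    """An internal precondition was violated (e.g. asymmetric input to NJ)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for logging."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
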