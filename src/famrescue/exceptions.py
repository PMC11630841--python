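"""Exception hierarchy for the rescue pipeline."""


class FamRescueError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FamRescueError):
    """A structure file could not be parsed in the requested format."""


class UnsupportedInputError(FamRescueError):
    """Input is parseable but outside the supported contract (e.g. multi-chain)."""


class MalformedModelError(FamRescueError):
    """A parsed model violates basic assumptions (e.g. residue with no atoms)."""


class ValidationError(FamRescueError):
    """A value violates a documented invariant (range, length, precondition)."""


class SchemaError(FamRescueError):
    """A tabular input is missing required columns."""


class TableParseError(FamRescueError):
    """A tabular input has an unparseable or invalid row."""


class DegenerateDataError(FamRescueError):
    """A statistic is undefined on this input (e.g. all paired differences zero)."""


class EmptyBankError(FamRescueError):
    """An operation requiring a non-empty template bank received an empty one."""


class BackendContractError(FamRescueError):
    """A prediction request violates the backend contract."""
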