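"""Exception hierarchy shared across the package."""


class DynalloError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DynalloError):
    """A file does not match the expected tabular layout (e.g. missing column)."""


class RowValidationError(DynalloError):
    """A row of an input file failed record-level validation."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ConfigError(DynalloError):
    """An invalid configuration value or unknown option."""


class DegenerateInputError(DynalloError):
    """Input data without enough variation for the requested fit."""
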