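"""Exception hierarchy for the editome package."""


class EditomeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EditomeError):
    """Invalid simulation or caller configuration."""


class GenerationError(EditomeError):
    """Synthetic-data generation could not satisfy the request."""


class FormatError(EditomeError):
    """Malformed or inconsistent input file."""


class InputError(EditomeError):
    """Inputs are individually valid but mutually inconsistent."""


class ContractError(EditomeError):
    """A precondition of an operation was violated by the caller."""
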