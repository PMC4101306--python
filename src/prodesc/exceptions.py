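"""Exception hierarchy shared across the package."""


class ProdescError(Exception):
    """Base class for all package errors."""


class SchemaError(ProdescError):
    """The declared variable schema is malformed or does not match the data."""


class ValidationError(ProdescError):
    """Data values violate the declared schema (bad codes, missing values)."""


class ParameterError(ProdescError):
    """An algorithm parameter is outside its admissible range."""


class ContractError(ProdescError):
    """A precondition of an operation is violated by its input."""


class NumericError(ProdescError):
    """A numerical computation produced non-finite or unusable values."""
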