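"""Exception hierarchy shared across dcakit modules."""


class DcakitError(Exception):
    """Base class for all dcakit errors."""


class ValidationError(DcakitError):
    """Malformed or inconsistent user input (bad file, bad labels, bad shapes)."""


class DomainError(ValidationError):
    """A numeric argument outside its mathematically valid domain."""


class NumericalError(DcakitError):
    """Failure of a numerical routine (non-convergence that cannot be recovered)."""
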