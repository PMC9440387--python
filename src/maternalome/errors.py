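"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition (bad stage label, bad rule, ...)."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class DegenerateProfileError(ValidationError):
    """A profile is constant (zero spread) and cannot be standardized."""
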