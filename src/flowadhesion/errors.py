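"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An input parameter violates a precondition (wrong sign, range, or shape)."""


class DomainError(ValueError):
    """Inputs are individually valid but fall outside a formula's domain."""
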