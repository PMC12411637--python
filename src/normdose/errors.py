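"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input value violates a physical or structural constraint."""


class MissingNuclideError(ValidationError):
    """Raised when an operation requires a nuclide that is absent from a vector.

    The offending nuclide name is available as :attr:`nuclide`.
    """

    def __init__(self, nuclide: str, context: str = ""):
        self.nuclide = nuclide
        msg = f"required nuclide {nuclide!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)
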