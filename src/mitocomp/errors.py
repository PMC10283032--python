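"""Exception hierarchy shared across the package."""


class MitocompError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MitocompError):
    """A sequence file could not be parsed into the expected model."""


class ValidationError(MitocompError):
    """An input object violates a structural precondition."""


class UndefinedDistanceError(MitocompError):
    """No comparable columns remain between two aligned sequences."""


class SaturationError(MitocompError):
    """Substitution proportions exceed the domain of the distance formula."""

    def __init__(self, P: float, Q: float):
        self.P = P
        self.Q = Q
        super().__init__(
            f"K2P distance undefined: saturation at P={P:.5f}, Q={Q:.5f} "
            f"(requires 1-2P-Q > 0 and 1-2Q > 0)"
        )
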