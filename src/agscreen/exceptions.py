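"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class InputDataError(ValueError):
    """Input data are malformed or inconsistent with each other."""


class EmptyPanelError(InputDataError):
    """Quality control removed every sample from a marker panel."""


class NumericalError(RuntimeError):
    """A linear system could not be solved reliably."""
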