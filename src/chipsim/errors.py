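"""Exception hierarchy shared across the package."""


class ChipSimError(Exception):
    """Base class for all chipsim errors."""


class InvalidInputError(ChipSimError, ValueError):
    """A physical quantity or record is outside its valid domain."""


class ConfigError(ChipSimError, ValueError):
    """A configuration file or layout is inconsistent."""


class StabilityError(ChipSimError, ValueError):
    """An explicit time step violates the stability contract.

    Carries a ``suggested_dt`` attribute with the largest admissible step.
    """

    def __init__(self, message: str, suggested_dt: float):
        super().__init__(message)
        self.suggested_dt = suggested_dt
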