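"""Exception types shared across the package."""


class ConfigurationError(Exception):
    """A parameter set, profile, or option is invalid or incomplete."""


class InputError(ValueError):
    """A caller-supplied value (command string, array, file) is malformed."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to advance the solution.

    Attributes
    ----------
    last_time : float
        Last time point the solver reached successfully.
    """

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time
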