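"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration block violates an invariant; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class UndefinedMetricError(ZeroDivisionError):
    """A ratio metric was requested with a zero/empty denominator."""
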