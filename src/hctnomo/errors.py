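"""Exception hierarchy shared across the toolkit."""


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class ConfigurationError(ValidationError):
    """A chart or model configuration is internally inconsistent."""


class ChartRangeError(ValidationError):
    """A value fell outside an axis range during a chart operation.

    Carries the name of the offending axis so graphical procedures can
    report which step failed.
    """

    def __init__(self, axis: str, value: float, lo: float, hi: float, step: str | None = None):
        self.axis = axis
        self.value = value
        self.step = step
        where = f" during step '{step}'" if step else ""
        super().__init__(
            f"value {value:g} is outside the '{axis}' axis range [{lo:g}, {hi:g}]{where}"
        )


class EventError(ValidationError):
    """An event in a sequence produced a physically impossible state.

    ``index`` identifies the offending event (0-based position in the list).
    """

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"event {index}: {message}")
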