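"""Exception types shared across pulsekit modules."""


class ConfigError(ValueError):
    """A configuration value is missing, inconsistent or out of range."""


class TraceTooShortError(ValueError):
    """The signal trace has too few samples for the requested operation."""


class DegenerateThresholdError(RuntimeError):
    """Auto-thresholding produced a zero scale; detection refuses to run."""


class InvertedPolarityError(ValueError):
    """Event rejected: positive-peak value does not exceed negative-peak value."""

    def __init__(self, v_pos: float, v_neg: float):
        self.reason = "inverted_polarity"
        super().__init__(
            f"inverted polarity: v_pos={v_pos:.6g} V <= v_neg={v_neg:.6g} V"
        )
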