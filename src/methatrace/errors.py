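"""Exception types shared across the package."""


class MethatraceError(Exception):
    """Base class for all package-specific errors."""


class QCError(MethatraceError):
    """Quality control left a sample with no usable injections."""

    def __init__(self, sample_ids):
        self.sample_ids = sorted(set(sample_ids))
        super().__init__(
            "no injections retained after QC for sample(s): "
            + ", ".join(self.sample_ids)
        )


class CalibrationError(MethatraceError):
    """A calibration segment cannot be constructed (e.g. missing standard)."""


class SchemaError(MethatraceError):
    """An input file does not match the expected column schema."""
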