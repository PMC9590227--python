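"""Exception hierarchy shared across the package."""


class MethrelError(Exception):
    """Base class for all package errors."""


class ParameterError(MethrelError, ValueError):
    """An argument or configuration value is invalid (negative variance, bad fraction, ...)."""


class SizingError(ParameterError):
    """Requested counts cannot be satisfied by the available probes/arrays."""


class CapabilityError(MethrelError):
    """A kernel requires a resource (OOB draws, control probes) the dataset lacks."""


class DegenerateDataError(MethrelError):
    """Zero-variance data for which the requested statistic is undefined."""


class DesignError(MethrelError):
    """A regression design is saturated or otherwise unusable."""


class FittingError(MethrelError):
    """A model fit failed to converge; carries diagnostics in the message."""


class MissingProbesError(MethrelError):
    """Predictor probes absent from the beta matrix under missing_policy='error'."""

    def __init__(self, probe_ids):
        self.probe_ids = list(probe_ids)
        preview = ", ".join(map(str, self.probe_ids[:10]))
        more = "" if len(self.probe_ids) <= 10 else f" (+{len(self.probe_ids) - 10} more)"
        super().__init__(f"{len(self.probe_ids)} model probes absent from beta matrix: {preview}{more}")


class ModelFormatError(MethrelError):
    """Predictor model CSV violates the expected format; reports the line number."""

    def __init__(self, line_no, message):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")
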