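"""Exception hierarchy for eegbench."""


class EEGBenchError(Exception):
    """Base class for all eegbench errors."""


class ParameterError(EEGBenchError, ValueError):
    """An operation was called with an out-of-contract parameter."""


class FormatError(EEGBenchError, ValueError):
    """A signal or sweep file could not be parsed."""


class ConfigError(EEGBenchError, ValueError):
    """A bench configuration is invalid."""


class DegenerateSignalError(EEGBenchError, ValueError):
    """A signal has zero variance where a nonzero spread is required."""


class ExtrapolationError(EEGBenchError, ValueError):
    """A frequency outside the tabulated range was requested without
    extrapolation enabled."""
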