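"""Exception hierarchy shared by all modules."""


class PLSCTError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PLSCTError, ValueError):
    """A tuning parameter is out of its admissible range."""


class ShapeError(PLSCTError, ValueError):
    """Array dimensions are inconsistent with the model or data."""


class PairingError(PLSCTError, ValueError):
    """Master/slave blocks that must be sample-paired are not."""


class DegenerateInputError(PLSCTError, ValueError):
    """Input carries no usable variance (constant X or y, exhausted rank)."""


class ConfigError(PLSCTError, ValueError):
    """A simulation or run configuration is invalid."""
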