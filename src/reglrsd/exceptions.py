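"""Exception hierarchy for data, protocol and numerical failures."""


class DataError(ValueError):
    """Raised when an input file or matrix violates the data contract."""


class ProtocolError(RuntimeError):
    """Raised when the subsampling evaluation protocol cannot proceed."""


class NumericalError(RuntimeError):
    """Raised when an iterative solver produces non-finite values."""
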