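"""Exception hierarchy.

``ConfigurationError`` — a calibration/rate-table/config document is invalid or
incomplete; ``InputError`` — a caller passed out-of-domain data; ``EstimationError`` —
an estimator was asked for a quantity its input cannot support.
"""


class PloidysimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PloidysimError):
    pass


class InputError(PloidysimError):
    pass


class EstimationError(PloidysimError):
    pass
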