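"""Exception hierarchy.

Validation failures split into two families: ``ParameterError`` for bad
arguments/configuration supplied by the caller, ``DataError`` for inputs whose
content violates an invariant (non-uniform sampling, zero baselines, ...).
``SchemaError`` marks malformed interchange files specifically. The CLI maps
any of these to exit code 2.
"""


class MotorUnitError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(MotorUnitError, ValueError):
    """An argument or configuration value is invalid; message names the field."""


class DataError(MotorUnitError, ValueError):
    """Input data violate a structural invariant."""


class SchemaError(DataError):
    """An interchange file does not match its declared schema."""
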