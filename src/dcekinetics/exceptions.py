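"""Exception hierarchy shared by all pipeline stages."""


class DCEError(Exception):
    """Base class for errors raised by dcekinetics."""


class InvalidInputError(DCEError, ValueError):
    """Malformed or inconsistent user input (grids, masks, tables, config)."""


class DegenerateParameterError(DCEError, ValueError):
    """A kinetic-parameter combination outside the model's domain
    (e.g. ve = 0 with ktrans > 0, or F <= 0 in the distributed-parameter model)."""


class NumericalError(DCEError, ArithmeticError):
    """A numerical routine failed to reach its requested accuracy."""
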