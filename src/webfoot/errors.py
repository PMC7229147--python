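"""Exception hierarchy with stable machine-readable codes.

Exit-status contract used by the CLI: 0 success, 2 input validation,
3 numerical/statistical failure.
"""


class WebfootError(Exception):
    code = "E_ERROR"
    exit_status = 1


class InputError(WebfootError):
    """Bad user input: files, formats, configuration."""

    code = "E_INPUT"
    exit_status = 2


class NewickParseError(InputError):
    code = "E_NEWICK"


class ValidationError(InputError):
    code = "E_VALIDATE"


class RenderError(InputError):
    code = "E_RENDER"


class NumericalError(WebfootError):
    """A statistic or estimate is undefined or failed on the given data."""

    code = "E_NUMERIC"
    exit_status = 3


class EstimationError(NumericalError):
    code = "E_ESTIMATE"


class DegenerateImageError(NumericalError):
    code = "E_DEGENERATE"


class UndefinedStatisticError(NumericalError):
    code = "E_UNDEFINED"
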