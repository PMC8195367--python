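"""Exception hierarchy.

Validation problems (bad files, bad labels, bad parameters) are kept
distinct from numerical/computational failures so callers — and the CLI
exit codes — can tell them apart.
"""


class TsccaError(Exception):
    """Base class for all package errors."""


class ValidationError(TsccaError):
    """Invalid input data or labels (bad file, duplicate ids, bad values)."""


class FormatError(ValidationError):
    """Malformed external file (ragged rows, wrong column count...)."""


class ParseError(ValidationError):
    """Unparseable cell content; message names the offending location."""


class ParameterError(ValidationError):
    """Out-of-range or inconsistent parameters."""


class ComputationError(TsccaError):
    """Numerical failure during model fitting or testing."""


class DegenerateInputError(ComputationError):
    """A score vector or input collapsed to exactly zero.

    Raised instead of silently re-randomizing; callers decide the
    restart policy (the solver exposes seeded restarts).
    """
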