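"""Exception hierarchy.

All input-validation failures raise :class:`ValidationError` so the CLI can
map them to exit code 2; everything else bubbles up as an unexpected failure
(exit code 1).
"""


class NutrishockError(Exception):
    """Base class for package errors."""


class ValidationError(NutrishockError, ValueError):
    """An input violated a documented precondition."""


class CalibrationError(NutrishockError, RuntimeError):
    """A root search for a distribution parameter failed to bracket or converge."""


class ScenarioError(ValidationError):
    """A scenario/config file is malformed; message names the offending field."""
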