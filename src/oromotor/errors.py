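"""Exception hierarchy for the oromotor pipeline."""


class OromotorError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(OromotorError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class DegenerateBaselineError(OromotorError):
    """Fewer than two baseline minima survived; the isosbestic fit is impossible."""


class SingularFitError(OromotorError):
    """The isosbestic channel is constant at the baseline minima."""


class NonpositiveBaselineError(OromotorError):
    """The fitted baseline F is <= 0 somewhere, so dF/F is undefined there."""


class RangeError(OromotorError):
    """A requested segment or window falls outside the recording."""


class InsufficientDataError(OromotorError):
    """Too few samples, events or trials to compute the requested quantity."""


class PairingError(OromotorError):
    """Paired comparison requested on unmatched samples."""


class QualityError(OromotorError):
    """Input data failed a quality gate (e.g. too many low-confidence frames)."""
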