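"""Exception hierarchy for bpmr.

All package errors derive from :class:`BpmrError` so callers can catch one
type; the subclasses distinguish user-configuration problems from bad input
data and from numerical failure modes that call for different remedies.
"""


class BpmrError(Exception):
    """Base class for all bpmr errors."""


class ConfigurationError(BpmrError):
    """A parameter, column mapping, or analysis config is invalid."""


class InputError(BpmrError):
    """Input data violates a structural requirement (e.g. duplicate IDs)."""


class InsufficientInstrumentsError(BpmrError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(BpmrError):
    """An instrument has zero exposure effect; the Wald ratio is undefined."""


class NumericalError(BpmrError):
    """A matrix operation failed beyond recoverable conditioning fixes."""
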