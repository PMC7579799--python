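"""Error hierarchy for difagree."""


class DifagreeError(Exception):
    """Base class for all package errors."""


class FormatError(DifagreeError):
    """Input file does not conform to the expected layout."""


class ParseError(DifagreeError):
    """A cell could not be parsed or is out of range."""


class ConfigError(DifagreeError):
    """Run configuration is inconsistent with the data or instrument."""


class DataError(DifagreeError):
    """Data violate a model precondition (e.g. an unobserved category)."""


class ConvergenceError(DifagreeError):
    """An iterative fit failed to converge.

    Carries the objective trajectory so the failure can be inspected.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = list(trajectory) if trajectory is not None else []


class FitError(DifagreeError):
    """A single-model maximum-likelihood fit failed (separation etc.)."""


class SimulationError(DifagreeError):
    """Monte-Carlo replication exceeded its retry budget."""
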