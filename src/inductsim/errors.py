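"""Exception hierarchy for the induction model."""


class InductSimError(Exception):
    """Base class for all package errors."""


class CalibrationInfeasibleError(InductSimError):
    """The printed summary anchors cannot be reproduced by any curve
    of the requested family (e.g. non-monotone proportions, or anchors
    exceeding the terminal sub-distribution mass)."""


class CalibrationNumericalError(InductSimError):
    """Root-finding for a curve parameter failed to converge."""


class AbsorbedStateError(InductSimError):
    """A transition probability was requested at a time where the
    cumulative incidence has already reached 1 (empty risk set)."""


class HorizonTooShortError(InductSimError):
    """The simulation horizon leaves more residual undelivered cohort
    mass than the configured threshold."""


class UndefinedSummaryError(InductSimError):
    """A summary statistic was requested for a trace with no events
    (e.g. mean time to vaginal delivery with no vaginal deliveries)."""


class ConfigurationError(InductSimError):
    """Invalid or inconsistent configuration / mismatched inputs."""
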