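"""Exception hierarchy for runfuel.

All runfuel-specific failures derive from :class:`RunfuelError` so callers
can catch the whole family; domain violations additionally derive from
``ValueError`` for compatibility with generic numeric code.
"""


class RunfuelError(Exception):
    """Base class for all runfuel errors."""


class DomainError(RunfuelError, ValueError):
    """An input lies outside the physical/physiologic domain of the model."""


class SupraAerobicError(DomainError):
    """A requested speed or intensity exceeds the aerobic ceiling.

    The model covers aerobic metabolism only; anaerobic power (phosphocreatine,
    glycolysis to lactate) is out of scope, so paces above the maximum aerobic
    speed are a hard error rather than an extrapolation.
    """


class FitDegeneracyError(RunfuelError, ValueError):
    """Too few or duplicated anchor points to determine the substrate fit."""


class UndefinedPartitionError(DomainError):
    """Substrate partition is undefined (zero total oxidation rate)."""


class ConfigError(RunfuelError, ValueError):
    """A configuration file or option is malformed or unknown."""


class PlanError(RunfuelError, ValueError):
    """A race or pacing plan is internally inconsistent or infeasible."""
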