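"""Exception hierarchy shared across the package."""


class PlasmaCnvError(Exception):
    """Base class for all plasmacnv errors."""


class CoordinateError(PlasmaCnvError):
    """A genomic interval falls outside its chromosome or window grid."""


class SizingError(PlasmaCnvError):
    """Window construction was asked for more windows than mappable positions."""


class NormalizationError(PlasmaCnvError):
    """Read-count normalization cannot proceed (e.g. all counts zero)."""


class CohortError(PlasmaCnvError):
    """A control cohort violates its preconditions (size, sex, window set)."""


class ConfigError(PlasmaCnvError):
    """An invalid pipeline or fixture configuration."""
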