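"""Exception hierarchy.

All package-specific failures derive from :class:`StemsoilError` so callers
can catch one base class at pipeline boundaries.
"""


class StemsoilError(Exception):
    """Base class for all stemsoil errors."""


class GeometryError(StemsoilError):
    """Invalid infiltration geometry (non-positive area, distance outside annuli)."""


class FluxError(StemsoilError):
    """Invalid flux value (negative deposition, non-positive throughfall water)."""


class FactorError(StemsoilError):
    """Water time factor outside its domain (must be >= 1)."""


class ScenarioError(StemsoilError):
    """Invalid deposition scenario (year ordering, negative fluxes, bad loads)."""


class DelayError(ScenarioError):
    """Steady-state delay incompatible with the scenario's year span."""


class TrajectoryError(StemsoilError):
    """Empty trajectory or year outside the trajectory range."""


class HorizonError(StemsoilError):
    """Invalid or unordered soil horizon intervals."""


class IncompleteProfileError(StemsoilError):
    """A depth profile is missing one or more required horizons."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"profile is missing horizons: {self.missing}")


class AlignmentError(StemsoilError):
    """Survey cells present in one survey but not the other."""

    def __init__(self, offenders):
        self.offenders = tuple(offenders)
        super().__init__(f"unmatched survey cells: {self.offenders}")


class AmbiguityError(StemsoilError):
    """Duplicate distances make a gradient ill-defined."""


class SchemaError(StemsoilError):
    """Input table does not match the declared column contract."""


class ConfigError(StemsoilError):
    """Configuration file invalid: unknown key or invariant-violating value."""
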