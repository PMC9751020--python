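"""Exception hierarchy shared across the package."""


class TfusimError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(TfusimError):
    """Inconsistent head geometry (e.g. skull thicker than the head)."""


class BoundsError(TfusimError):
    """A geometric object does not fit inside the simulation grid."""


class ConfigError(TfusimError):
    """Invalid configuration. Carries the full list of violations."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class NumericalError(TfusimError):
    """Numerical instability detected during a solve (NaN/Inf)."""


class ConvergenceError(TfusimError):
    """An iterative procedure failed to reach its tolerance."""


class MechanicalFailureError(TfusimError):
    """Sonophore leaflets collapsed onto each other (Z <= -Delta/2)."""


class RangeError(TfusimError):
    """A query fell outside the tabulated/valid range."""
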