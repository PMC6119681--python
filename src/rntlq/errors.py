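"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument is outside the physical domain of an operation."""


class DegeneratePlateError(ValueError):
    """A plate cannot yield survival fractions (roles missing, or the
    control signal does not exceed the cell-free background)."""


class NeverEffectiveError(DomainError):
    """The exposure never exceeds the effectiveness threshold, so no
    critical time exists (alpha * R0 * T_av <= threshold)."""


class PackingError(RuntimeError):
    """Rejection sampling failed to place all cells without overlap."""


class FitError(RuntimeError):
    """A survival-curve fit could not be performed."""


class ConfigError(ValueError):
    """A run configuration is inconsistent or incomplete."""
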