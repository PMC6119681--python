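"""Closed-form dosimetry of an exponentially decaying, uniformly mixed source.

A radionuclide dissolved in a well of culture medium delivers dose at a rate
that decays with the physical decay constant λ:

    Ḋ(t) = Ḋ₀ e^{−λt},        Ḋ₀ = A₀ Ē k / m,

where A₀ is the initial activity (Bq), Ē the mean energy per decay (MeV),
k the joules-per-MeV constant and m the medium mass (kg).  All emitted
energy is assumed absorbed locally (the medium is large compared with the
mean beta range is *not* required — this is the standard well-scale
full-absorption model).  Integrating over an irradiation window T gives the
total dose, the cumulative number of disintegrations Ã, and the per-day
decay fractions used to bin hit counts in time.

Times are in hours throughout the public interface; disintegration counts
convert λ to per-second internally.  λ = 0 is a valid constant-rate limit
(external-beam exposures flow through the same code path), handled by
series limits rather than errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as C
from .errors import DomainError

__all__ = [
    "DecaySource",
    "IrradiationWindow",
    "DoseRecord",
    "decay_constant",
    "initial_dose_rate",
    "dose_rate_at",
    "total_dose",
    "cumulative_decays",
    "activity_for_target_dose",
    "daily_activity_fractions",
    "dose_record",
]


def decay_constant(half_life_h: float) -> float:
    """Decay constant λ = ln2 / T½, per hour."""
    if half_life_h <= 0:
        raise DomainError(f"half-life must be positive, got {half_life_h}")
    return C.LN2 / half_life_h


@dataclass(frozen=True)
class DecaySource:
    """A radionuclide source uniformly mixed in a well.

    Parameters
    ----------
    initial_activity_bq
        Activity at t = 0, in becquerel.
    half_life_h
        Physical half-life in hours.
    mean_energy_mev
        Mean energy emitted per decay, MeV.
    medium_mass_kg
        Mass of the absorbing medium, kg (200 µl of water = 2.0e-4 kg).
    """

    initial_activity_bq: float
    half_life_h: float = C.Y90_HALF_LIFE_H
    mean_energy_mev: float = C.Y90_MEAN_ENERGY_MEV
    medium_mass_kg: float = C.WELL_MEDIUM_MASS_KG
    label: str = ""

    def __post_init__(self) -> None:
        if self.initial_activity_bq < 0:
            raise DomainError("initial activity must be >= 0")
        if self.half_life_h <= 0:
            raise DomainError("half-life must be > 0")
        if self.mean_energy_mev <= 0:
            raise DomainError("mean energy per decay must be > 0")
        if self.medium_mass_kg <= 0:
            raise DomainError("medium mass must be > 0")

    @property
    def decay_constant_per_h(self) -> float:
        return decay_constant(self.half_life_h)


@dataclass(frozen=True)
class IrradiationWindow:
    """Duration of an exposure, hours."""

    duration_h: float = C.INCUBATION_HOURS

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise DomainError("window duration must be > 0")


@dataclass(frozen=True)
class DoseRecord:
    """Summary dosimetry of one source over one window."""

    initial_dose_rate_gy_per_h: float
    total_dose_gy: float
    cumulative_decays: float
    per_day_activity_fractions: list[float] = field(default_factory=list)


def initial_dose_rate(source: DecaySource) -> float:
    """Initial dose rate Ḋ₀ = A₀ Ē k / m, in Gy/h.

    Full local absorption of the mean emitted energy: every decay deposits
    Ē in the medium mass m.
    """
    joules_per_s = source.initial_activity_bq * source.mean_energy_mev * C.MEV_TO_J
    return joules_per_s / source.medium_mass_kg * C.HOURS_TO_SECONDS


def dose_rate_at(initial_rate_gy_per_h: float, lam_per_h: float, t_h: float) -> float:
    """Dose rate Ḋ₀ e^{−λt} at time t (hours)."""
    if t_h < 0:
        raise DomainError(f"time must be >= 0, got {t_h}")
    return initial_rate_gy_per_h * math.exp(-lam_per_h * t_h)


def total_dose(
    initial_rate_gy_per_h: float, lam_per_h: float, window: IrradiationWindow
) -> float:
    """Total dose over the window, (Ḋ₀/λ)(1 − e^{−λT}) in Gy.

    λ = 0 returns the constant-rate limit Ḋ₀·T rather than erroring, so an
    external-beam exposure is just a zero-λ source.
    """
    T = window.duration_h
    if lam_per_h == 0.0:
        return initial_rate_gy_per_h * T
    if lam_per_h < 0:
        raise DomainError("decay constant must be >= 0")
    return initial_rate_gy_per_h * (-math.expm1(-lam_per_h * T)) / lam_per_h


def cumulative_decays(source: DecaySource, window: IrradiationWindow) -> float:
    """Cumulative activity Ã = A₀(1 − e^{−λT})/λ — the total number of
    disintegrations in the window (λ in per-second units for the count)."""
    lam_s = source.decay_constant_per_h / C.HOURS_TO_SECONDS
    T_s = window.duration_h * C.HOURS_TO_SECONDS
    return source.initial_activity_bq * (-math.expm1(-lam_s * T_s)) / lam_s


def activity_for_target_dose(
    target_dose_gy: float,
    window: IrradiationWindow,
    half_life_h: float = C.Y90_HALF_LIFE_H,
    mean_energy_mev: float = C.Y90_MEAN_ENERGY_MEV,
    medium_mass_kg: float = C.WELL_MEDIUM_MASS_KG,
) -> float:
    """Initial activity (Bq) that delivers ``target_dose_gy`` in the window.

    Exact inverse of ``initial_dose_rate`` composed with ``total_dose``;
    the round trip is an identity to floating-point precision.
    """
    if target_dose_gy < 0:
        raise DomainError("target dose must be >= 0")
    unit = DecaySource(
        initial_activity_bq=1.0,
        half_life_h=half_life_h,
        mean_energy_mev=mean_energy_mev,
        medium_mass_kg=medium_mass_kg,
    )
    dose_per_bq = total_dose(initial_dose_rate(unit), unit.decay_constant_per_h, window)
    return target_dose_gy / dose_per_bq


def daily_activity_fractions(
    lam_per_h: float, n_days: int, window: IrradiationWindow
) -> list[float]:
    """Fraction of all decays in the window that fall in each 24 h day.

    fraction_n = (e^{−λ·24(n−1)} − e^{−λ·24n}) / (1 − e^{−λT}); the fractions
    sum to one.  λ = 0 gives the uniform limit 1/n_days.
    """
    if n_days <= 0:
        raise DomainError("n_days must be positive")
    if abs(n_days * 24.0 - window.duration_h) > 1e-9 * max(1.0, window.duration_h):
        raise DomainError(
            f"window of {window.duration_h} h does not split into {n_days} whole days"
        )
    if lam_per_h == 0.0:
        return [1.0 / n_days] * n_days
    denom = -math.expm1(-lam_per_h * window.duration_h)
    out = []
    for n in range(1, n_days + 1):
        num = math.exp(-lam_per_h * 24.0 * (n - 1)) - math.exp(-lam_per_h * 24.0 * n)
        out.append(num / denom)
    return out


def dose_record(
    source: DecaySource, window: IrradiationWindow, n_days: int | None = None
) -> DoseRecord:
    """Convenience: full dosimetry summary for one source and window."""
    r0 = initial_dose_rate(source)
    lam = source.decay_constant_per_h
    fracs: list[float] = []
    if n_days is not None:
        fracs = daily_activity_fractions(lam, n_days, window)
    return DoseRecord(
        initial_dose_rate_gy_per_h=r0,
        total_dose_gy=total_dose(r0, lam, window),
        cumulative_decays=cumulative_decays(source, window),
        per_day_activity_fractions=fracs,
    )
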