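"""Plate-assay survival fractions and linear-quadratic fitting.

A 96-well colorimetric viability assay (MTS-type) measures optical density
(OD) proportional to the number of metabolically active cells.  Survival
fraction in a test well is the background-corrected OD ratio

    SF = (OD_test − OD_cell-free) / (OD_control − OD_cell-free),

with the control and cell-free means pooled per plate.  Dose–response
curves are assembled across replicate plates and fitted to the LQ law
−ln SF = αD + βD² (or its protraction-corrected form with a fixed G) by
weighted least squares in log-survival space with non-negativity bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, lsq_linear

from .errors import DegeneratePlateError, DomainError, FitError

__all__ = [
    "PlateAssay",
    "SurvivalCurve",
    "LQFit",
    "sf_from_od",
    "build_survival_curve",
    "fit_lq",
    "alpha_beta_ratio",
    "read_plate_csv",
    "write_plate_csv",
]

ROLES = ("test", "control", "cell_free", "empty")
ROW_LABELS = list("ABCDEFGH")
COL_LABELS = [str(i) for i in range(1, 13)]


@dataclass
class PlateAssay:
    """A 96-well optical-density grid with per-well role and dose.

    ``grid`` is the 8×12 OD matrix; ``role_map`` holds one of
    test/control/cell_free/empty per well; ``dose_map`` carries the dose
    (Gy) of every test well (NaN elsewhere).
    """

    grid: np.ndarray
    role_map: np.ndarray
    dose_map: np.ndarray
    cell_line: str = ""
    modality: str = "EBRT"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.role_map = np.asarray(self.role_map, dtype=object)
        self.dose_map = np.asarray(self.dose_map, dtype=float)
        if self.grid.shape != (8, 12):
            raise DomainError(f"plate grid must be 8x12, got {self.grid.shape}")
        if self.role_map.shape != (8, 12) or self.dose_map.shape != (8, 12):
            raise DomainError("role and dose maps must be 8x12")
        if np.any(self.grid < 0):
            raise DomainError("optical densities must be >= 0")
        bad = set(np.unique(self.role_map)) - set(ROLES)
        if bad:
            raise DomainError(f"unknown well roles: {bad}")
        test = self.role_map == "test"
        if np.any(test & ~np.isfinite(self.dose_map)):
            raise DegeneratePlateError("every test well needs a dose")
        if not np.any(self.role_map == "control") or not np.any(
            self.role_map == "cell_free"
        ):
            raise DegeneratePlateError("plate needs >=1 control and >=1 cell-free well")

    def control_mean(self) -> float:
        return float(self.grid[self.role_map == "control"].mean())

    def cell_free_mean(self) -> float:
        return float(self.grid[self.role_map == "cell_free"].mean())


def sf_from_od(od_test: float, od_control: float, od_free: float) -> float:
    """Survival fraction from optical densities (raw ratio, may fall
    outside [0, 1] with noisy plates; clipping is the caller's choice).

    Affine-invariant: a common offset on all three ODs cancels.
    """
    denom = od_control - od_free
    if not denom > 0:
        raise DegeneratePlateError(
            "control OD must exceed cell-free OD (degenerate plate)"
        )
    return (od_test - od_free) / denom


@dataclass
class SurvivalCurve:
    """Dose-response curve: per-dose mean SF with standard errors."""

    doses_gy: np.ndarray
    sf: np.ndarray
    sf_se: np.ndarray
    n_replicates: np.ndarray
    sf_raw: list[np.ndarray] = field(default_factory=list)  # per-dose well values
    n_clipped: int = 0
    cell_line: str = ""
    modality: str = ""


def build_survival_curve(plates: PlateAssay | list[PlateAssay]) -> SurvivalCurve:
    """Assemble a survival curve from one or more replicate plates.

    Control and cell-free ODs are averaged per plate (plates differ in
    handling); each test well then yields one SF via the background-
    corrected ratio, and wells are pooled across plates per dose.  The
    standard error is the sample SE over pooled replicate wells.  Doses
    are returned sorted ascending regardless of plate layout.
    """
    if isinstance(plates, PlateAssay):
        plates = [plates]
    if not plates:
        raise DegeneratePlateError("no plates supplied")
    per_dose: dict[float, list[float]] = {}
    n_clipped = 0
    for plate in plates:
        if not np.any(plate.role_map == "control") or not np.any(
            plate.role_map == "cell_free"
        ):
            raise DegeneratePlateError(
                "plate lacks control or cell-free wells"
            )
        ctrl = plate.control_mean()
        free = plate.cell_free_mean()
        test = plate.role_map == "test"
        for od, dose in zip(plate.grid[test], plate.dose_map[test]):
            sf = sf_from_od(od, ctrl, free)
            if sf < 0.0 or sf > 1.0:
                n_clipped += 1
            per_dose.setdefault(round(float(dose), 9), []).append(sf)
    doses = np.array(sorted(per_dose))
    values = [np.array(per_dose[d]) for d in doses]
    sf = np.array([v.mean() for v in values])
    sf_se = np.array(
        [v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0 for v in values]
    )
    return SurvivalCurve(
        doses_gy=doses,
        sf=sf,
        sf_se=sf_se,
        n_replicates=np.array([len(v) for v in values]),
        sf_raw=values,
        n_clipped=n_clipped,
        cell_line=plates[0].cell_line,
        modality=plates[0].modality,
    )


@dataclass
class LQFit:
    """Fitted LQ parameters.

    ``beta_eff`` is the coefficient of D² actually estimated: β for an
    acute exposure, G·β for a protracted one fitted with the plain design;
    when a fixed G is supplied the underlying β = beta_eff is reported for
    the G-scaled design column.
    """

    alpha: float
    beta_eff: float
    covariance: np.ndarray
    g: float = 1.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def alpha_se(self) -> float:
        return math.sqrt(max(self.covariance[0, 0], 0.0))

    @property
    def beta_se(self) -> float:
        return math.sqrt(max(self.covariance[1, 1], 0.0))

    @property
    def alpha_beta_ratio(self) -> float:
        return alpha_beta_ratio(self)


def alpha_beta_ratio(fit: "LQFit") -> float:
    """α/β in Gy — the dose at which linear and quadratic kill are equal."""
    if fit.beta_eff <= 0:
        raise DomainError("alpha/beta undefined: quadratic coefficient is zero")
    return fit.alpha / fit.beta_eff


def fit_lq(
    curve: SurvivalCurve,
    model: str = "LQ",
    g: float = 1.0,
    sf_floor: float = 1e-4,
    weighted: bool = True,
    space: str = "log",
) -> LQFit:
    """Fit −ln SF = αD + Gβ D² with non-negativity bounds on (α, β).

    ``model`` is "LQ" (G = 1) or "extended_LQ" (fixed ``g`` supplied).
    The default fit is weighted least squares in log-survival space, with
    per-dose weights propagated from the SF standard errors; wells at or
    below ``sf_floor`` are floored there and down-weighted, with the count
    reported in the diagnostics.  ``space="sf"`` instead fits the survival
    fractions directly with a nonlinear least-squares pass (sensitivity
    option).  The parameter covariance is the weighted normal-equation
    inverse, inflated by the reduced chi-square when the scatter exceeds
    the nominal errors.
    """
    if model == "LQ":
        g = 1.0
    elif model != "extended_LQ":
        raise FitError(f"unknown model {model!r}")
    if not 0.0 < g <= 1.0:
        raise DomainError("G must lie in (0, 1]")
    doses = np.asarray(curve.doses_gy, dtype=float)
    sf = np.asarray(curve.sf, dtype=float)
    if len(np.unique(doses)) < 3:
        raise FitError("need >= 3 distinct doses")
    if np.allclose(sf, 1.0):
        raise FitError("no dose response: all survival fractions are 1")

    floored = sf <= sf_floor
    sf_eff = np.where(floored, sf_floor, sf)
    y = -np.log(sf_eff)
    X = np.column_stack([doses, g * doses * doses])

    se = np.asarray(curve.sf_se, dtype=float)
    if weighted and np.any(se > 0):
        var_y = (np.where(se > 0, se, se[se > 0].mean()) / sf_eff) ** 2
        var_y[floored] *= 1e4  # floored points carry almost no information
    else:
        var_y = np.ones_like(y)
    w = 1.0 / var_y
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    if np.linalg.matrix_rank(Xw) < 2:
        raise FitError("singular design matrix")
    res = lsq_linear(Xw, yw, bounds=(0.0, np.inf))
    alpha, beta = res.x

    if space == "sf":
        # nonlinear refinement on SF directly
        def model_sf(d, a, b):
            return np.exp(-(a * d + g * b * d * d))

        sigma = np.where(se > 0, se, max(se.max(), 1e-3)) if weighted else None
        try:
            popt, _ = curve_fit(
                model_sf,
                doses,
                sf_eff,
                p0=[max(alpha, 1e-6), max(beta, 1e-8)],
                sigma=sigma,
                bounds=(0.0, np.inf),
                maxfev=10000,
            )
            alpha, beta = popt
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise FitError(f"nonlinear SF-space fit failed: {exc}") from exc

    resid = yw - Xw @ np.array([alpha, beta])
    dof = max(len(y) - 2, 1)
    chi2_red = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    cov = xtx_inv * max(chi2_red, 1.0) if weighted else xtx_inv * chi2_red
    return LQFit(
        alpha=float(alpha),
        beta_eff=float(beta),
        covariance=cov,
        g=g,
        diagnostics={
            "n_floored": int(floored.sum()),
            "n_clipped_wells": curve.n_clipped,
            "chi2_reduced": chi2_red,
            "dof": dof,
            "space": space,
            "weighted": weighted,
            "model": model,
        },
    )


# --- plate CSV dialect ------------------------------------------------------
# OD grid: first row/column are well labels (A-H, 1-12).  Layout CSV: same
# shape; cells hold "control", "cell_free", "empty" or "test:<dose Gy>".


def write_plate_csv(plate: PlateAssay, od_path: str | Path, layout_path: str | Path) -> None:
    od = pd.DataFrame(plate.grid, index=ROW_LABELS, columns=COL_LABELS)
    od.to_csv(od_path, index_label="well")
    layout = np.empty((8, 12), dtype=object)
    for i in range(8):
        for j in range(12):
            role = plate.role_map[i, j]
            if role == "test":
                layout[i, j] = f"test:{plate.dose_map[i, j]:g}"
            else:
                layout[i, j] = role
    pd.DataFrame(layout, index=ROW_LABELS, columns=COL_LABELS).to_csv(
        layout_path, index_label="well"
    )


def read_plate_csv(
    od_path: str | Path,
    layout_path: str | Path,
    cell_line: str = "",
    modality: str = "EBRT",
) -> PlateAssay:
    od = pd.read_csv(od_path, index_col=0)
    layout = pd.read_csv(layout_path, index_col=0)
    grid = od.to_numpy(dtype=float)
    role_map = np.empty((8, 12), dtype=object)
    dose_map = np.full((8, 12), np.nan)
    for i in range(8):
        for j in range(12):
            cell = str(layout.iloc[i, j]).strip()
            if cell.startswith("test:"):
                role_map[i, j] = "test"
                dose_map[i, j] = float(cell.split(":", 1)[1])
            else:
                role_map[i, j] = cell
    return PlateAssay(
        grid=grid, role_map=role_map, dose_map=dose_map,
        cell_line=cell_line, modality=modality,
    )
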