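"""Synthetic inputs: plates from a ground-truth survival law, activity
ladders, and small packed geometries for fast simulator tests.

The plate generator emulates the column-wise dose-gradient design of a
96-well viability experiment: each dose occupies one column of test
wells, one column holds unirradiated controls and one holds cell-free
background wells.  Optical densities follow

    OD = OD_free + (OD_control − OD_free) · SF(D; α, β, G) + noise,

with additive normal noise on OD (default SD 0.03, a typical plate-reader
repeatability figure — the wet experiment states no noise magnitude, so
this is a declared stand-in) and an optional multiplicative lognormal
component.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .dosimetry import DecaySource
from .errors import ConfigError, DomainError
from .microdosimetry import WellGeometry, pack_cells
from .protraction import CellLineRadioParams, log_cell_kill
from .survival import PlateAssay

__all__ = ["GroundTruth", "gen_plate", "gen_activity_ladder", "gen_geometry_fixture"]


@dataclass(frozen=True)
class GroundTruth:
    """Generative survival law and noise model for synthetic plates."""

    alpha: float
    beta: float
    g: float = 1.0
    cell_line: str = "synthetic"
    modality: str = "EBRT"
    od_control_mean: float = 0.9
    od_free_mean: float = 0.1
    od_sd_additive: float = 0.03
    od_sd_multiplicative: float = 0.0

    def __post_init__(self) -> None:
        if self.od_control_mean <= self.od_free_mean:
            raise DomainError("control OD mean must exceed cell-free OD mean")
        if self.od_sd_additive < 0 or self.od_sd_multiplicative < 0:
            raise DomainError("noise SDs must be >= 0")

    def survival(self, dose_gy: float) -> float:
        return float(
            np.exp(-log_cell_kill(self.alpha, self.beta, self.g, dose_gy))
        )

    @property
    def params(self) -> CellLineRadioParams:
        return CellLineRadioParams(
            name=self.cell_line, alpha=self.alpha, beta=self.beta
        )


def gen_plate(
    truth: GroundTruth,
    doses_gy: list[float],
    n_replicate_wells: int = 8,
    seed: int = 0,
) -> PlateAssay:
    """One synthetic 96-well plate under the ground-truth law.

    Dose k occupies column k (rows 0..n_replicate_wells−1 as test wells);
    the last two columns hold control and cell-free wells with the same
    replicate count.  With zero noise, the background-corrected OD ratio
    returns SF(D) exactly.
    """
    if not 1 <= n_replicate_wells <= 8:
        raise ConfigError("replicate wells per column must be 1..8")
    if len(doses_gy) > 10:
        raise ConfigError(
            f"{len(doses_gy)} dose columns do not fit: 12 columns minus "
            "control and cell-free"
        )
    rng = np.random.default_rng(seed)
    grid = np.zeros((8, 12))
    role_map = np.full((8, 12), "empty", dtype=object)
    dose_map = np.full((8, 12), np.nan)
    span = truth.od_control_mean - truth.od_free_mean

    def noisy(mean_od: float, n: int) -> np.ndarray:
        od = np.full(n, mean_od)
        if truth.od_sd_multiplicative > 0:
            od = od * rng.lognormal(0.0, truth.od_sd_multiplicative, n)
        if truth.od_sd_additive > 0:
            od = od + rng.normal(0.0, truth.od_sd_additive, n)
        return np.maximum(od, 0.0)

    rows = slice(0, n_replicate_wells)
    for j, dose in enumerate(doses_gy):
        mean_od = truth.od_free_mean + span * truth.survival(dose)
        grid[rows, j] = noisy(mean_od, n_replicate_wells)
        role_map[rows, j] = "test"
        dose_map[rows, j] = dose
    grid[rows, 10] = noisy(truth.od_control_mean, n_replicate_wells)
    role_map[rows, 10] = "control"
    grid[rows, 11] = noisy(truth.od_free_mean, n_replicate_wells)
    role_map[rows, 11] = "cell_free"
    return PlateAssay(
        grid=grid,
        role_map=role_map,
        dose_map=dose_map,
        cell_line=truth.cell_line,
        modality=truth.modality,
    )


def gen_activity_ladder(kind: str = "HDR") -> list[DecaySource]:
    """The ten-rung per-well activity ladder of the decaying-source series.

    HDR: 28.8–288 kBq per well; LDR: 4.8–48 kBq (2.4 MBq/ml × 20 µl at the
    top rung).  Sources carry the default well dosimetry constants.
    """
    kind = kind.upper()
    if kind == "HDR":
        activities = C.HDR_ACTIVITIES_KBQ
    elif kind == "LDR":
        activities = C.LDR_ACTIVITIES_KBQ
    else:
        raise ConfigError(f"ladder kind must be LDR or HDR, got {kind!r}")
    return [
        DecaySource(initial_activity_bq=a * 1e3, label=f"{kind}-{i + 1}")
        for i, a in enumerate(activities)
    ]


def gen_geometry_fixture(
    n_cells: int, seed: int = 0, well_radius_mm: float = 0.5
) -> WellGeometry:
    """Small packed monolayer for sub-second transport tests.

    A reduced well radius keeps the source column small so that a few
    thousand primaries already give nonzero hit counts; the fill volume is
    scaled with the floor area so the medium depth stays at the standard
    ~6 mm.
    """
    if n_cells > 500:
        raise ConfigError("fixture limited to 500 cells; use pack_cells directly")
    volume_ul = C.WELL_VOLUME_UL * (well_radius_mm / C.WELL_RADIUS_MM) ** 2
    if n_cells == 0:
        return WellGeometry(
            well_radius_mm=well_radius_mm,
            well_height_mm=volume_ul * 1e9 / (np.pi * (well_radius_mm * 1e3) ** 2) / 1e3,
            cell_diameter_um=C.CELL_DIAMETER_UM,
            nucleus_diameter_um=C.NUCLEUS_DIAMETER_UM,
            cell_centers_um=np.empty((0, 3)),
            seed=seed,
        )
    return pack_cells(
        n_cells, well_radius_mm=well_radius_mm, seed=seed,
        well_volume_ul=volume_ul,
    )
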