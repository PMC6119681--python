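"""Physical constants, nuclide presets and cell-line reference data.

Nuclear constants are data, not code: everything here can be overridden at
call sites, and two ⁹⁰Y half-life conventions ship side by side because the
literature mixes them (64.1 h for well dosimetry, the rounded "2.7 days"
= 64.8 h for the critical-time tables).
"""

from __future__ import annotations

import math

# --- unit conversions ------------------------------------------------------
MEV_TO_J = 1.602176634e-13  # J per MeV
HOURS_TO_SECONDS = 3600.0
LN2 = math.log(2.0)

#: Mean energy expended in water per ion pair formed, eV (ICRU value for
#: electrons; used only for the derived ionisation estimate in voxel tallies).
W_ION_PAIR_EV = 33.97

# --- yttrium-90 ------------------------------------------------------------
#: Half-life used for well dosimetry (h).
Y90_HALF_LIFE_H = 64.1
#: The "2.7 day" convention (h); its rounded decay constant is 0.0107 /h.
Y90_HALF_LIFE_27D_H = 64.8
#: Mean energy per decay (MeV) consistent with the well dosimetry tables.
Y90_MEAN_ENERGY_MEV = 0.9267
#: Spectrum-average beta energy (MeV) quoted for the emission spectrum.
Y90_SPECTRUM_MEAN_MEV = 0.933
#: Beta endpoint energy (MeV).
Y90_MAX_ENERGY_MEV = 2.280

# --- experiment geometry ---------------------------------------------------
#: Mass of 200 µl of water-equivalent culture medium (kg).
WELL_MEDIUM_MASS_KG = 2.0e-4
WELL_VOLUME_UL = 200.0
WELL_RADIUS_MM = 3.25
WELL_PITCH_MM = 9.0
CELL_DIAMETER_UM = 15.0
NUCLEUS_DIAMETER_UM = 5.0
N_CELLS_PER_WELL = 5000
INCUBATION_DAYS = 8
INCUBATION_HOURS = 192.0

# --- DNA repair kinetics ---------------------------------------------------
#: Average sublethal-damage repair half-life (h) used for the G-infinity
#: estimate when cell-line-specific kinetics are unknown.
DEFAULT_REPAIR_HALF_LIFE_H = 1.5
#: Repair rate constant (per hour) used for the isotope comparison table.
ISOTOPE_TABLE_REPAIR_RATE_PER_H = 0.42

#: Threshold constant in the critical-time / critical-dose-rate relations.
#: Kept at the conventional printed value 0.693 rather than ln 2 so that
#: published four-significant-figure tables reproduce exactly.
CRIT_THRESHOLD = 0.693

# --- cell-line radiobiological parameters ----------------------------------
# alpha (per Gy), beta (per Gy^2) for the acute external-beam fits; for the
# decaying-source high-dose-rate series the quadratic coefficient is the
# *effective* one (G folded in).  Doubling times in hours.
CELL_LINES = {
    "HCT116": {
        "alpha_ebrt": 0.1981,
        "beta_ebrt": 0.0439,
        "alpha_y90": 0.0350,
        "gbeta_y90": 0.0009,
        "doubling_time_h": 20.0,
    },
    "SW48": {
        "alpha_ebrt": 0.1511,
        "beta_ebrt": 0.0376,
        "alpha_y90": 0.0265,
        "gbeta_y90": 0.0008,
        "doubling_time_h": 24.0,
    },
    "HT29": {
        "alpha_ebrt": 0.0842,
        "beta_ebrt": 0.0239,
        "alpha_y90": 0.0145,
        "gbeta_y90": 0.0005,
        "doubling_time_h": 23.0,
    },
}

#: Initial dose rate (Gy/h) of the top rung of the high-dose-rate series as
#: used in the published critical-time table.
R0_HDR_TABLE = 0.792

#: Constant dose rate (Gy/h) of the 6 MV linac beam.
EBRT_DOSE_RATE_GY_PER_H = 277.0

# --- activity ladders (kBq per well, descending as published) --------------
HDR_ACTIVITIES_KBQ = [288.0, 259.0, 230.0, 202.0, 173.0, 144.0, 115.0, 86.4, 57.6, 28.8]
LDR_ACTIVITIES_KBQ = [48.0, 43.2, 38.4, 33.6, 28.8, 24.0, 19.2, 14.4, 9.60, 4.80]

#: Published closed-form total doses (Gy) for the two ladders.
HDR_DOSES_GY = [62.3, 56.1, 49.9, 43.6, 37.4, 31.2, 24.9, 18.7, 12.5, 6.20]
LDR_DOSES_GY = [10.4, 9.30, 8.30, 7.20, 6.20, 5.20, 4.20, 3.10, 2.10, 1.00]

#: Published critical-time table: (lambda /h as printed, alpha /Gy,
#: R0 Gy/h, doubling time h, T_crit days, R_crit Gy/h).
TCRIT_REFERENCE = {
    "HCT116": (0.0107, 0.1981, 0.792, 20.0, 5.883, 0.1749),
    "HT29": (0.0107, 0.0842, 0.792, 23.0, 3.095, 0.3578),
    "SW48": (0.0107, 0.1511, 0.792, 24.0, 5.538, 0.1911),
}

# --- physical half-lives of common therapy / imaging nuclides (hours) ------
ISOTOPE_HALF_LIVES_H = {
    "Bi-213": 45.6 / 60.0,
    "F-18": 1.83,
    "Tc-99m": 6.01,
    "Re-188": 17.0,
    "Sm-153": 46.3,
    "Cu-67": 61.8,
    "Y-90": 64.1,
    "Lu-177": 6.65 * 24.0,
    "I-131": 8.02 * 24.0,
    "Ra-223": 11.43 * 24.0,
    "P-32": 14.27 * 24.0,
}
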