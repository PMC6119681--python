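# Methods

## Dosimetry model

A radionuclide uniformly mixed in a well is treated as a point-kinetics
source: activity A(t) = A₀e^(−λt), dose rate Ḋ(t) = A₀Ēk e^(−λt)/m with
Ē the mean energy per decay, k the joules-per-MeV constant and m the
medium mass.  Every decay is assumed to deposit its mean energy locally
("full absorption"); this is the standard well-scale model and is the only
dimensionally consistent reading of the dose-rate relation Ḋ = A/m when
the printed dose rates (0.77 Gy/h at 288 kBq in 200 µl) are to be
recovered.  Integrals over the window T give the total dose
(Ḋ₀/λ)(1−e^(−λT)) and the cumulative decay count Ã = A₀(1−e^(−λT))/λ
(λ per second for the count).  λ = 0 is handled as a series limit, so a
constant-rate external beam flows through the same interfaces.

Defaults: ⁹⁰Y half-life 64.1 h and Ē = 0.9267 MeV per decay, medium mass
2.0·10⁻⁴ kg (200 µl of water; the 20 µl activity spike is ignored).  These
reproduce the published activity-ladder doses to ≤ 1%, but the exact
constants behind those tables are not printed, so agreement is checked at
2% (with a 0.05 Gy absolute floor that matches the rounding of the
smallest printed entries, e.g. 1.037 Gy printed as 1.00 ± 0.1).  A second
convention, the "2.7 day" half-life (64.8 h, rounded decay constant
0.0107 h⁻¹), is used by the critical-time table; with it all six published
T_crit/R_crit values reproduce to four significant figures, which the
rounded 0.0107 itself does not achieve.  Both presets ship in
`constants.py`; neither is hard-coded in the physics.

## Extended LQ and protraction

Survival follows −ln SF = αD + GβD².  The Lea–Catcheside factor

G = (2/D²)∫₀ᵀ Ḋ(t) dt ∫₀ᵗ Ḋ(t′) e^(−μ(t−t′)) dt′

is evaluated in closed form for Ḋ(t) = Ḋ₀e^(−λt); the inner integral's
lower limit is 0 because the source is added at t = 0.  Numerically the
bracket divided by (λ−μ) is a divided difference of f(s) = (1−e^(−sT))/s
between s = λ+μ and s = 2λ; within a relative 10⁻⁶ of the removable
singularity λ = μ it is replaced by −f′ at the midpoint, which keeps the
closed form within 10⁻⁶ of a nested-quadrature evaluation everywhere
(verified in the tests).  μ = 0 returns exactly 1.  For constant-rate
exposures G = 2(x−1+e^(−x))/x² with x = μT, with a series branch below
x = 10⁻⁶.  The asymptote is G∞ = λ/(λ+μ) = τ½/(T½+τ½).

The critical-time and critical-dose-rate thresholds use the printed
constant 0.693 rather than ln 2: the published four-significant-figure
table is internally consistent only with 0.693 (ln 2 shifts the HT29
R_crit from 0.3578 to 0.3579).  The threshold constant is an argument, so
ln 2 is one keyword away.  When αR₀T_av ≤ 0.693 no critical time exists
and `NeverEffectiveError` is raised rather than returning NaN.

Repair kinetics: the default repair half-life is 1.5 h (an average
literature value; the cell lines' own kinetics were not measured).  The
isotope comparison table uses μ = 0.42 h⁻¹ as stated where it is defined,
although the parenthetical gloss accompanying that figure ("ln 0.5 over
15 h") is arithmetically inconsistent with it; 0.42 h⁻¹ is taken as the
operative value.  The equieffective-dose solver equates −ln SF between
modalities and takes the unique positive quadratic root; with positive
coefficients no tie is possible.

A note on printed precision: G∞ for ⁹⁰Y at τ½ = 1.5 h is 0.02262, which
the source tables truncate to 0.022 (round-to-two-significant-figures
would give 0.023).  The package always reports the computed value.

## Plate assays and fitting

Survival fractions use the background-corrected OD ratio with control and
cell-free means pooled per plate; test wells are pooled across plates per
dose, and the per-dose SE is the sample SE over pooled wells.  Fits are
weighted least squares on −ln SF against (D, GD²) with non-negativity
bounds (scipy `lsq_linear`), weights propagated from the SF standard
errors by the delta method.  SF values at or below a 10⁻⁴ floor (possible
with noisy ODs) are floored and down-weighted by 10⁴, with the count
reported in the diagnostics — the original analysis does not state how it
handled non-positive ratios.  The covariance is the weighted
normal-equation inverse inflated by the reduced χ² when scatter exceeds
the nominal errors; this keeps 3-SE intervals conservative when replicate
SEs are estimated from few wells.  A nonlinear SF-space fit is provided as
a sensitivity option since the original fitting space is unstated.

## Microdosimetry simulator

Deliberately reduced physics: straight tracks, continuous-slowing-down
energy deposition from a coarse embedded table of electron collision
stopping power in liquid water (10 keV–2.3 MeV, log-log interpolated),
no multiple scattering, no delta rays, no bremsstrahlung (~1% radiative
loss at these energies).  The ⁹⁰Y spectrum is a 64-bin table built from
the allowed Fermi shape times the first-forbidden-unique factor (q²+p²)
with a non-relativistic Coulomb correction for Z = 40; a single solved
exponential tilt calibrates the table mean to the 0.933 MeV spectrum
average (the coarse shape alone lands ≈ 4% high), leaving the 2.280 MeV
endpoint untouched.  Electrons below the 10 keV table floor deposit
locally (residual range 2.5 µm).

Geometry defaults are standard 96-well dimensions: radius 3.25 mm, fill
height ≈ 6.0 mm from the 200 µl volume, 9 mm pitch for the cross-fire
layout; the source experiments state only the volume.  Cells are 15 µm
spheres with concentric 5 µm nuclei, centres at z = 7.5 µm (monolayer),
packed by rejection sampling (≈ 2.7% floor coverage at 5000 cells).
A compartment scores a hit when a track chord deposits more than a
configurable threshold (default: any deposition).  Tracks terminate at
their CSDA range or on crossing the well boundary; no backscatter from
the plastic is modelled.  Raw tallies scale linearly to the cumulative
activity Ã, giving Ñ (mean hits per nucleus) with a Poisson standard
error, and the daily decay fractions convert Ñ into per-day hit bins that
conserve the total exactly.  With Ñ = 21 and λ = 0.0107 h⁻¹ the day-5 bin
is 1.95 hits, so the rate first drops below the ≈ 2 hits/day
double-strand-break threshold on day 5 — consistent with the reported
"below ≈ 2 after ≈ 5 days" (a rounded-bin reading can place this on day
6; the package scans the exact bins).

Problem sizes: the default test fixture is 200 cells in a 0.5 mm-radius
well with 10⁴–3·10⁴ primaries, and the pipeline default is 2·10⁴
primaries — sizes chosen so the statistical property suite (conservation,
seed determinism, linearity within 3 Poisson SDs, cross-section ratios
within a factor of two) runs in seconds while leaving relative Poisson
errors well below the tested tolerances.  Absolute condensed-history
tallies (hits per nucleus ≈ 295/21 for beam/decay exposures, ionisation
counts, the 6% cross-fire fraction) are *not* reproducible under
straight-track physics and are not asserted; the simulator reports its
own values with uncertainties instead.  The cross-fire experiment embeds
the wells in uniform water (no plate walls or air), which is why its
external fractions (~1–2%) undershoot the condensed-history 6% figure;
only the order of magnitude and the symmetry/shielding structure are
meaningful.

Ionisation counts are a derived estimate, energy/W with W = 33.97 eV per
ion pair, and are labelled as such; a per-interaction count has no meaning
without explicit ionisation transport.

## Synthetic data

Plates are generated from OD = OD_free + (OD_ctrl−OD_free)·SF(D) + noise,
with additive normal OD noise of SD 0.03 by default (typical plate-reader
repeatability; the wet experiment quotes no noise figure) and an optional
multiplicative lognormal term.  Control/cell-free OD means default to
0.9/0.1 — arbitrary, and cancelled by the background-corrected OD ratio,
so they affect nothing downstream.  Dose ladders default to
1–9 Gy in 1 Gy steps for the beam arm and to the LDR/HDR activity ladders
(4.8–48 and 28.8–288 kBq per well) for the decay arms.  What the
generator does *not* emulate: plate-edge effects, spatial OD gradients,
pipetting covariance between neighbouring wells, repopulation during the
window, and assay nonlinearity at high cell density.  Passing recovery
tests therefore demonstrate correctness of the estimator under the stated
noise model, not robustness to those real-world artefacts.

## Design choices and limitations

- Time is in hours across the public API; microdosimetry uses µm
  internally and mm in configs.
- Replication of the published design is under-specified at the well
  level ("repeated twice/three times"); the generator exposes both
  plate-level and well-level replication, and the recovery experiments in
  the tests use two plates of eight replicate wells at nine doses.
- The quadratic coefficient fitted for decaying-source arms is reported
  as `beta_eff` (= Gβ) because a single-window experiment cannot separate
  G from β; supplying a fixed G to the extended fit recovers β itself.
- Low-response fits (the LDR arm) are reported with diagnostics rather
  than suppressed; their published α values came from fits described as
  insignificant and are not certified.
- The external-beam arm is treated analytically (G = 1, constant rate);
  photon transport is out of scope.
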