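# rntlq

Radiobiological modelling of radionuclide therapy with decaying sources,
benchmarked against external-beam exposure, for in-vitro well-plate
experiments.

When a beta emitter such as ⁹⁰Y is dissolved in a culture well, the dose
rate is not constant: it decays with the physical half-life, so by the time
the nominal dose has been delivered most of it arrived early and slowly.
Whether that dose kills cells as effectively as the same number of gray
delivered in two minutes by a linac depends on the competition between
damage accrual and sublethal-damage repair.  `rntlq` packages the standard
quantitative machinery for that question:

- **Dosimetry of a uniformly mixed decaying source.**  Dose rate
  Ḋ(t) = Ḋ₀e^(−λt) with Ḋ₀ = A₀Ēk/m; total dose D = (Ḋ₀/λ)(1−e^(−λT));
  cumulative decays Ã = A₀(1−e^(−λT))/λ; per-day decay fractions; and the
  inverse problem (what activity delivers a target dose in 8 days).
- **Extended linear-quadratic survival.**  −ln SF = αD + GβD², where the
  Lea–Catcheside factor G ∈ (0,1] attenuates the quadratic (two-track)
  term when repair (rate μ) outpaces damage accumulation.  Closed forms
  for exponentially decaying sources, constant-rate beams, and the
  fully-decayed asymptote G∞ = τ½/(T½+τ½); critical time/dose-rate
  thresholds T_crit = −(1/λ)ln(0.693/(αR₀T_av)), R_crit = 0.693/(αT_av);
  and an equieffective-dose solver across modalities.
- **Plate-assay survival fitting.**  Background-corrected survival
  fractions from 96-well optical densities,
  SF = (OD_test−OD_free)/(OD_control−OD_free), curve assembly across
  replicate plates, and bounded weighted least-squares LQ fits with
  covariance and α/β.
- **Simplified cell-scale microdosimetry.**  A packed monolayer of
  spherical cells (15 µm, 5 µm nucleus) on the floor of a cylindrical
  well, ⁹⁰Y spectrum sampling, straight-track continuous-slowing-down
  transport with tabulated stopping powers, per-compartment hit/energy
  tallies scaled to cumulative activity, daily hit binning
  N/nucleus(day n) = (Aₙ/Ã)Ñ, voxel dose actors and an adjacent-well
  cross-fire experiment.  This is deliberately *not* a condensed-history
  Monte Carlo code: it trades absolute tallies for fast, reproducible hit
  statistics.
- **Synthetic data.**  Plates generated from a ground-truth survival law
  with configurable noise, the LDR/HDR activity ladders, and small packed
  geometries — everything the pipeline needs without wet-lab input.

## Worked example

```python
from rntlq.dosimetry import DecaySource, IrradiationWindow, initial_dose_rate, total_dose
from rntlq.protraction import (CellLineRadioParams, equieffective_dose,
                               g_infinity, lea_catcheside_G_constant_rate)

src = DecaySource(initial_activity_bq=288e3)          # top HDR rung, 200 µl
r0 = initial_dose_rate(src)
d = total_dose(r0, src.decay_constant_per_h, IrradiationWindow(192.0))
print(f"R0 = {r0:.3f} Gy/h, D(8 d) = {d:.1f} Gy")
print(f"G_inf(Y-90) = {g_infinity(64.8, 1.5):.4f}")
print(f"G(EBRT 8 Gy @ 277 Gy/h) = {lea_catcheside_G_constant_rate(8, 277, 0.4621):.4f}")
ebrt = CellLineRadioParams("HT29", alpha=0.0842, beta=0.0239)
y90  = CellLineRadioParams("HT29", alpha=0.0145, beta=0.0005)
print(f"equieffective dose = {equieffective_dose(ebrt, 1.0, 8.0, y90, 1.0):.1f} Gy")
```

prints

```
R0 = 0.770 Gy/h, D(8 d) = 62.3 Gy
G_inf(Y-90) = 0.0226
G(EBRT 8 Gy @ 277 Gy/h) = 0.9956
equieffective dose = 53.4 Gy
```

The 288 kBq well starts at 0.77 Gy/h and accumulates 62.3 Gy in eight
days.  For ⁹⁰Y with a 1.5 h repair half-life, G∞ ≈ 0.023: protraction all
but eliminates the quadratic kill component, while the two-minute
external-beam exposure keeps G ≈ 1.  At the fitted HT29 parameters, an
acute 8 Gy beam dose is matched only by ~53 Gy of decaying-source dose —
the core dose-rate effect the package quantifies.

The same computations are scriptable from the shell:

```sh
rntlq tcrit                 # critical-time table for all three cell lines
rntlq dosecalc --ladder HDR # dose/dose-rate/decays for the activity ladder
rntlq isotable              # G-infinity across common therapy nuclides
rntlq run --config cfg.yaml # full synthetic pipeline with a manifest
```

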