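# tsmod

Design, calibration and quantification toolkit for genetically encoded
FRET-based molecular tension sensors.

Tension sensor modules (TSMods) — two fluorescent proteins joined by an
unstructured polypeptide and inserted into a load-bearing protein such as
vinculin — report molecular forces through FRET: stretching the polypeptide
separates the fluorophores and lowers the transfer efficiency.  Using a
sensor quantitatively requires a calibration, i.e. the map from measured
efficiency to force and extension.  `tsmod` implements a first-principles
calibration from polymer physics rather than single-molecule pulling
experiments, plus the surrounding analysis workflow.

## The model

The extensible domain is a worm-like chain with contour length
`Lc = N · 0.38 nm` (N residues) and persistence length `Lp`.  The ensemble
FRET efficiency is the average of the Förster relation over the chain's
end-to-end distance distribution `p(r)`:

    E(F) = ∫ p_F(r) · 1 / (1 + ((r + 2·Rfp)/R0)^6) dr,

where `R0` is the pair's Förster radius, `Rfp` the fluorophore radius
(collinear offset), and a constant axial force `F` tilts the distribution
by the orientation-averaged Boltzmann weight `sinh(F·r/kBT)/(F·r/kBT)`.
Sensor extension is `rz(F) = ⟨r⟩_F − ⟨r⟩_0`.  The radial density is a
moment-calibrated interpolation whose three shape parameters reproduce the
chain's exact ⟨r²⟩, ⟨r⁴⟩, ⟨r⁶⟩ (Legendre transfer-matrix recursion) with a
Marko–Siggia stretching-energy tail; it is validated against an
independent Monte Carlo chain sampler to sub-percent accuracy
(`tsmod.validation`).

With `R0` and `Rfp` fixed from the literature, `Lp` is the single free
parameter and is fit to unloaded FRET-vs-length measurements by
chi-squared minimisation with studentized-bootstrap confidence intervals
(`tsmod.calibration`).  The calibrated model then yields force-response
curves, sensor performance metrics (dynamic range ΔFRET, target force
Ftarget, target extension rz,target) and full design-space roadmaps
(`tsmod.roadmap`).  The package also includes a structural spring-network
model of focal adhesions that distinguishes force-controlled from
extension-controlled protein loading (`tsmod.fa_model`), quantitative FRET
from three-cube microscopy and fluorometer spectra (`tsmod.quantify`,
`tsmod.spectra`), and ground-truth synthetic data generators for all input
types (`tsmod.synth`).

## Worked example

```python
import numpy as np
from tsmod import (SensorDesign, ExtensibleDomain, get_pair, unloaded_fret,
                   compute_metrics, fret_to_force_extension)

design = SensorDesign(get_pair("clover-mruby2"),
                      ExtensibleDomain("GGSGGS", n_repeats=9, lp=0.48))
print(f"unloaded FRET efficiency: {unloaded_fret(design):.3f}")
m = compute_metrics(design, noise_floor=0.05)
print(f"dynamic range dFRET:      {m.delta_fret:.3f}")
print(f"target force Ftarget:     {m.f_target:.2f} pN")
print(f"target extension rz:      {m.rz_target:.2f} nm")
measured = [0.05, 0.10, 0.15]
res = fret_to_force_extension(measured, design)
for e, f, x in zip(measured, res.force, res.extension):
    print(f"E = {e:.2f}  ->  F = {f:.2f} pN, rz = {x:.2f} nm")
```

prints

```
unloaded FRET efficiency: 0.192
dynamic range dFRET:      0.142
target force Ftarget:     2.14 pN
target extension rz:      1.42 nm
E = 0.05  ->  F = 4.29 pN, rz = 2.85 nm
E = 0.10  ->  F = 2.83 pN, rz = 1.49 nm
E = 0.15  ->  F = 1.70 pN, rz = 0.60 nm
```

i.e. the nine-repeat Clover–mRuby2 sensor at the cellular persistence
length (`Lp` = 0.48 nm) rests at 19% efficiency, loses its signal to the
5% noise floor over ~4.3 pN, and is therefore centred on the 1–6 pN loads
borne by vinculin; a measured efficiency converts directly to a force and
an extension.

## Command line

An umbrella `tsmod` command exposes the workflows:
`calibrate` (Lp fit + bootstrap CI), `predict` (force-response CSV),
`roadmap` (design-space sweep), `fa-model` (control-regime classification),
`fret-images` (per-adhesion efficiencies from TIFF triplets), `ratio-a`
(spectrofluorometric efficiency) and `synth` (ground-truth synthetic
inputs).  Run `tsmod --help` for options.

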