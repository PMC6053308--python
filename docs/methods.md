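# Methods

This note documents the models implemented in `tsmod`, the numerical
choices behind them, the synthetic-data conditions the test suite runs
under, and the limits of what those tests demonstrate.

## Chain mechanics and FRET averaging (`tsmod.mechanics`)

**Model.**  The extensible domain is a semiflexible polymer with
persistence length `Lp` and contour length `Lc = N · lc_per_residue`
(default 0.38 nm per residue, the standard polypeptide backbone value;
configurable because different conventions between 0.34 and 0.40 nm exist
in the literature).  The optical readout couples to the end-to-end
distance `r` through the point-dipole Förster relation
`E(rc) = 1/(1 + (rc/R0)^6)` with `rc = r + 2·Rfp`: the fluorophore radii
enter as a collinear additive offset.  That is the simplest geometry
consistent with a single effective radius per fluorophore; whether the
offset should instead sit inside an orientational average is not
experimentally constrained, and the collinear choice maximally preserves
the monotone link between chain extension and efficiency.

**Radial density.**  Exact closed forms for the worm-like-chain end-to-end
density exist only in limits, so the density is an interpolating family

    p(x) ∝ x² (1−x²)^A exp( −B·x²/(1−x²) + C·x² + D·x⁴ ),  x = r/Lc,

with the tail strength pinned, `B = (Lc/2Lp) / (1 + b/2Lp)` (bond length
`b = Lc/N`; `b = 0` for the continuous chain).  The pin makes the
near-full-extension tail integrate the Marko–Siggia stretching energy
`∫F dx ≈ kBT·Lc/(4Lp(1−x))`, softened toward the freely-jointed power-law
tail that a coarse discrete chain actually has.  The three free parameters
`A`, `C`, `D` are solved (cached per `(Lp, Lc, N)`) so the density's
⟨r²⟩, ⟨r⁴⟩ and ⟨r⁶⟩ equal the exact chain moments computed by a Legendre
transfer-matrix recursion — the discrete N-bond Kratky–Porod chain when
the residue count is known (a polypeptide *is* a discrete chain; its
bending constant is chosen so the discrete ⟨r²⟩ equals the continuous-WLC
value), the Hermans–Ullman continuous hierarchy otherwise.  Fallbacks
(dropping `D`, then freeing `B`) cover extreme stiffness regimes where the
pinned-tail root solve fails.

**Force.**  A constant axial force tilts the density of the end-to-end
vector by `exp(F·z/kBT)`; integrating over orientations of an isotropic
chain gives the radial weight `sinh(F·r/kBT)/(F·r/kBT)`.  This
re-weighting is exact for any isotropic chain because the force couples
only to the end-to-end vector, so the only approximation in loaded
averages is the unloaded density itself.  Extension is reported as
`rz(F) = ⟨r⟩_F − ⟨r⟩_0`, a pure polymer quantity independent of `Rfp`.
Thermal energy defaults: 4.28 pN·nm (310 K, cellular) and 4.11 pN·nm
(298 K, bench).

**Validation.**  `tsmod.validation` is an independent brute-force sampler:
unloaded chains are drawn exactly (von Mises–Fisher Markov steps), loaded
chains are equilibrated by vMF Gibbs sweeps.  Agreement for 20–60 residue
chains at the persistence lengths of interest is ≲0.2% on ⟨r⟩ and ≲1e-3
on E unloaded, and within ~0.5%/2e-3 under 2–10 pN loads — comfortably
inside the 1%/0.005 envelope the tests assert.

**Numerics.**  Ensemble averages use fixed 600-node Gauss–Legendre
quadrature in self-normalising form (norm errors cancel in the ratio);
pointwise normalisation uses adaptive quadrature with breakpoints packed
toward full extension.  All force weights are computed in log space.

## Persistence-length fitting (`tsmod.calibration`)

The fit minimises `χ²(Lp) = Σ((E_model(N_i;Lp) − E_i)/σ_i)²`; points
without quoted uncertainties get unit weights.  Because `E_model` is
smooth and monotone in `Lp`, each series precomputes the model on a
220-point logarithmic grid over 0.05–20 nm, splines it, pre-scans for the
global minimum and polishes with bounded Brent; the surrogate is within
~1e-7 efficiency of the exact model, making bootstrap replicates
essentially free.  Sensitivity variants release `R0` or `Rfp` as a second
parameter via an outer profile search.  Joint fits pool unloaded
FRET-length points with FRET-force points of a reference construct under
a single `Lp`.

**Uncertainty.**  Confidence intervals come from a residual bootstrap
(200 resamples by default): measured lengths stay fixed and
leverage-adjusted standardized residuals are resampled.  Resampling whole
(length, E) points is available but demonstrably underestimates the
sampling variance on small per-length aggregate tables (the protocols that
resample whole measurements operate on dozens of replicates per length,
a granularity aggregate tables no longer carry).  The interval itself is
the symmetric studentized bootstrap-t — each replicate deviation scaled by
its own curvature-based standard error — which restores near-nominal
coverage where percentile (≈85%) and BCa (≈88%) intervals undercover on
nine-point series; measured coverage of the default method is ≈95% over
180 independent synthetic series.

## Sensor metrics and roadmap (`tsmod.roadmap`)

The dynamic range ΔFRET is the drop from the unloaded efficiency to a 5%
noise floor (the practical detection limit of cellular FRET imaging); the
target force is half the force at which the efficiency reaches the floor
(`Ftarget = F_floor/2`, the midpoint of the functional range), and the
target extension is defined analogously (`rz,target = rz_floor/2`).  The
floor crossing is found by bisection on the monotone E(F) curve to 1e-6 pN.
Designs whose unloaded efficiency is at or below the floor report zero
dynamic range; very short designs whose fully stretched efficiency is
still above the floor report infinite target force, flagged as
unreachable — both states are physical, not errors.  The default roadmap
grid spans the reported range of unstructured-polypeptide mechanics
(`Lp` log-spaced over 0.1–10 nm) and lengths of 6–96 residues in steps of
six; sweeping outside those bounds warns but proceeds.  Inversion of the
calibration curve (measured E → force, extension) uses monotone PCHIP
interpolation of a densified response curve; efficiencies above the
unloaded value map to negative loads by linear extrapolation at the origin
and are flagged for exclusion.

## Focal-adhesion structural model (`tsmod.fa_model`)

Adhesions are modelled as two molecular strata in series, each a parallel
bundle of linear springs: sensor elements (the tagged protein) and linker
elements (everything else load-bearing).  For regime classification the
sensors occupy their characteristic stratum — adhesion proteins sit at
defined nanoscale heights — while linkers scatter randomly (seeded);
fully random placement is also available but makes the two strata
statistically identical, which erases the force-controlled corner of the
phase diagram.

The two input modes deliberately differ in coupling physics:

* an **extension input** is a rigid displacement clamp (myosin step,
  actin polymerisation increment): elements within a stratum share its
  extension, and strata divide the input in inverse proportion to their
  stiffness;
* a **force input** is transmitted serially through the stack (every
  stratum carries the full force) and is shared *equally* among the
  parallel elements of a stratum, i.e. the lateral molecular coupling is
  treated as compliant and fluid-like rather than rigid.  With rigid
  lateral coupling a force input would load each molecule in proportion
  to its stiffness and could masquerade as extension control; force-
  balance sharing is what makes a pure force input read as
  force-controlled for every composition, which is the experimentally
  motivated behaviour the model must reproduce.

Classification mirrors the three-sensor experiment: the ensemble is run
for a trio of sensor-stiffness multipliers (0.5×, 1×, 2×) and the regime
is read from the coefficients of variation of the per-variant *mean*
sensor force versus mean extension (margin 2× to call a regime, otherwise
"mixed").  A pooled single-variant statistic cannot work: for a linear
spring `F = k·δ`, so pooled force and extension CVs are identical by
construction.  Energy consistency (`Σ ½kδ²` equals the work of the bulk
input) and per-stratum force balance are asserted on every solve.

## FRET quantification (`tsmod.quantify`, `tsmod.spectra`)

Three-cube imaging: bleed-through fractions come from donor-only and
acceptor-only references (20 equal-count intensity bins, median ratio per
bin, intensity-weighted average — robust to shot noise), the corrected
FRET image is `Fc = If − dbt·Id − abt·Ia`, and the pixel efficiency is
`E = Fc/(Fc + G·Id)`, the sensitized-emission form in which `G` converts
donor quenching into sensitized-emission units.  `G` is calibrated by
least squares across donor–acceptor fusions of distinct known
efficiencies.  Negative `Fc` is flagged, never clipped; acceptor-intensity
gates (published values: 1000–40000 for mTFP1–Venus, 600–24000 for
Clover–mRuby2) invalidate pixels rather than raising.  Adhesion summaries
use label masks (external, or the naive Otsu segmenter provided) with the
standard single-FA filters (area > 0.5 µm², axis ratio > 1.5), and the
line-scan metric resamples axial efficiency profiles to a normalised FA
length, averages, and reports the least-squares slope in %/FA.

Spectrofluorometry implements the (ratio)A method,
`E = [εA(λAex)/εD(λDex)]·[If(λAem)/Ia(λAem) − εA(λDex)/εA(λAex)]`, with
extinction spectra obtained by scaling measured absorbance shapes to the
known maximal coefficients (mTFP1 64,000; Venus 93,000; Clover 111,000;
mRuby2 113,000 M⁻¹cm⁻¹) — concentration and path length cancel.

## Synthetic data (`tsmod.synth`) — what passing tests show

Every generator is a pure function of (spec, seed).  Length series carry
Gaussian replicate noise (defaults: nine lengths of 1–9 repeats, replicate
s.d. 0.03 averaged over 9 replicates, i.e. s.e.m. 0.01 — the precision the
underlying cellular protocols were powered for); image triplets follow the
exact three-cube algebra with optional Poisson shot noise; spectra are
Gaussian bands satisfying the (ratio)A identity with the donor emission
truncated before the acceptor peak; gradient phantoms are noise-free
geometric bars.  Passing round trips therefore demonstrate the *inverse
consistency* and statistical calibration of the estimators — they do not
exercise optical blur, chromatic aberration, uneven illumination, read
noise, segmentation error or biological heterogeneity, all of which real
data add on top.

## Problem sizes

The shipped test suite and the acceptance script use Monte Carlo ensembles
of 2,000–60,000 chains, 30–50 synthetic series with 200 bootstrap
resamples each, 200 network realizations per phase-diagram cell, and
128×128 synthetic images; these sizes put every stochastic check several
standard errors inside its tolerance while keeping a full run in the
minutes range on a single core.

## Known limitations

* The chain model has no excluded volume, no sequence-specific effects and
  no crowding; environment dependence enters only through the fitted `Lp`.
* Single-`R0` point-dipole FRET: no orientation factor (κ²) modelling and
  no spectral-overlap computation of `R0`.
* The force ensemble is the constant-force (Gibbs) ensemble; constant-
  extension measurements of very short chains would differ.
* The FA model is zero-dimensional per stratum: no spatial geometry,
  turnover, or motor kinetics; linear springs only in the classification
  sweeps (a Marko–Siggia tangent stiffness can be supplied for the
  stiffness–force relation through the element stiffness values).
* Folded-domain sensors with non-monotonic force-extension curves are out
  of scope.
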