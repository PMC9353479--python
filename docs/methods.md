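# Methods

This note documents the model behind `chipsim`, its assumptions, the shipped
parameter values, and what the tests do and do not demonstrate.

## Geometry

The device cross-section is seven parallel channels, mirror-symmetric about
the central tumor gel: endothelial medium channels (#1/#7), astrocyte
collagen channels (#2/#6), communication medium channels (#3/#5), tumor
collagen channel (#4). The published protocol fixes the channel height
(200 µm photoresist) but not the widths or culture length; the shipped
defaults — 1.0 mm channel width and 6.0 mm length — are calibrated choices
of this package, logged as such, and overridable in the config. Every
simulation runs on the half cross-section (#1–#3 plus half of #4) with a
zero-flux symmetry boundary at the #4 midline.

Each medium channel is fed by punched reservoir ports holding the loaded
liquid (120 µL daily refresh per medium channel in culture; 120 µL cold PBS
/ 60 µL collagenase during extraction). A channel itself holds only 1.2 µL,
so the reservoirs carry ~99% of the liquid but sit *lengthwise* away from
the cross-section — the physical basis of the microscale-confinement effect
modeled below.

The Transwell comparator is derived from the chip layout: identical cell
counts, identical total medium volume, modeled as a single 1-D vertical
column of uniform cross-section (default 1.9 cm², the 24-well footprint)
with the insert membrane 0.9 mm above the well floor, treated as freely
permeable. The bTME cells sit in a thin slab at the insert floor, the tumor
readout is the bottom 200 µm of the column (height-matched to the chip
channel). A 1-D column rather than two perfectly mixed boxes is used because
the comparison is about spatial gradients, not just volumes.

## Diffusion coefficients

Radius from mass: r[Å] = 0.66·M[Da]^(1/3) (compact-globule scaling).
Free diffusivity: Stokes–Einstein at T = 310.15 K, µ = 8.9e-4 Pa·s.
Gel hindrance: Ogston obstruction exp(−√φ·r/r_f) with φ = 0.125 and
r_f = 200 nm for 2 mg/mL type 1 collagen.

For collagenase the extraction scenario uses the reference values
8.4e-11 m²/s (medium) and 8.35e-11 m²/s (collagen) directly, so the
simulation is anchored to the published coefficients; the package's own
chain (M = 100 kDa, the midpoint of the 63–130 kDa enzyme range, at the
default conditions) reproduces the free value within 1% and the gel/medium
ratio exactly to 3 significant figures. The exact (M, T, µ) triple behind
the reference free value is not recoverable from the published numbers and
is deliberately not guessed. Cytokine diffusivities are always computed from
their molecular weights (serpin E1 44 kDa, IL-8 8 kDa, SPP-1 32.9 kDa).

The conversion 0.5 mg/mL ↔ 7e-3 mol/m³ implies M ≈ 71.4 kDa; the
mass/molar conversion functions therefore take the molecular weight
explicitly instead of hard-coding either number.

## Interstitial flow

Drainage of the 60 µL reservoir head is a lumped first-order relaxation:
ΔP(t) = ΔP₀·e^(−t/τ), u(t) = κ·ΔP(t)/(µ·L) with κ = 1e-13 m²
(literature-typical for 2 mg/mL collagen) and L the astrocyte-gel width.
τ = 200 s is a calibrated lumped constant placing the 5% equilibrium
criterion at 600 s; it is prescribed, not derived from κ, because the
physical device drains through the whole port/channel network and not only
through the gel slab. The default port area (1.65 mm², a ~1.4 mm punch)
sets ΔP₀ ≈ 357 Pa and hence u₀ ≈ 4.0e-2 mm/s, just above the stored
reference protective threshold of 3.95e-2 mm/s. That threshold is kept as a
constant to compare against and is never re-derived.

Reservoir liquid volumes are book-kept by integrating the Darcy flux
through the gel cross-section, so the velocity history and the reservoir
record are exactly flux-consistent; total liquid is conserved.

## Transport solver

Explicit conservative finite volumes on a 1-D chain of segments:

* diffusion — central differences, harmonic-mean interface diffusivity
  (handles medium/gel jumps and zero-diffusivity segments);
* advection — first-order upwind on the faces of the flow path
  (#1 → #2 → #3). The face where the path meets the stagnant tumor gel
  carries no advective flux: fluid leaving through the communication
  channel's ports is not explicitly modeled, so solute swept along the path
  piles up against that interface and enters the tumor gel by diffusion.
  This reproduces the observed behavior of the full 2-D simulation —
  enzyme is concentrated toward the center channel while flow runs and
  relaxes back afterwards — at 1-D cost. Numerical diffusion u·Δx/2 at the
  default resolution is of the same order as the physical diffusivity only
  inside the thin stagnation layer; tests that check attenuation against
  exp(−Pe) closed forms use a finer grid where that matters;
* sources — per-compartment cell counts × per-cell rates, spread uniformly;
* reservoirs — finite well-mixed compartments exchanging with their channel
  through a lumped conductance g = D·(w·h)/(ℓ/2) (diffusion along half the
  culture length to the ports). g is of order 1e-14 m³/s, so reservoirs are
  nearly decoupled on the hour scale; this single number carries the
  chip-vs-Transwell enrichment effect and is the crudest part of the model.

Stability/positivity contract: dt ≤ 0.4·min(Δx²/2D, Δx/|u|); an oversized
step is refused with the largest admissible step in the error. Default
Δx = 5 µm. The update is a convex combination of non-negative values, so
concentrations stay non-negative; with sources off and no Dirichlet
segments, total amount (cells + reservoirs) is conserved to round-off.

## Scenarios

**Collagenase extraction** (1800 s): enzyme at 1.0 mg/mL in channel #3 and
its reservoir, protective flow per the drainage model, concentrations in
mg/mL. The protocol description states a 1.0 mg/mL working solution while
the simulation section quotes 0.5 mg/mL (7e-3 mol/m³); the package defaults
to 1.0 and both are reachable via `collagenase.load_mg_ml`. Metrics: first
time the channel-#2 mean exceeds a "reach" threshold — defined here as 1%
of the initial load, a stated convention since no threshold is published,
with 0.5% and 5% sensitivity values logged; the time the channel-#4 mean
spends inside the 0.5–2.5 mg/mL activating window (counted on the 10 s
sampling grid); the peak #4 concentration; the head equilibrium time; and
the time-integrated #2 exposure used by the protection comparison. If the
window is never entered the duration is reported as 0 with a warning, not
an exception. When no crossing occurs within the run, the run length is
reported as a lower bound on the arrival time.

**Cytokine enrichment** (24 h): sources are the bTME compartments only —
endothelial cells in #1 (48,000/channel from 60 µL at 8e5/mL) and
astrocytes in #2 (1,200/channel at 1e6/mL) — matching the published
simulation layout in which secretion originates from the bTME region;
tumor cells are present but not sources. The per-cell rates are taken as
*relative* strengths (the printed per-cell units are physically implausible
as absolute values), with one global scale per solute; consequently only
ratio-type outputs are quantitative and the enrichment ratio is provably
invariant under rate rescaling (tested). Arrival at the tumor channel is
the first sample where the #4 mean exceeds 1% of the concurrent #2 mean.
The Transwell arm runs the same solutes with identical total cell counts in
the matched column.

## Assay estimators

* Viability: mean of per-ROI live/(live+dead) fractions ± SEM (matches the
  published n = 65 / n = 21 ROI-wise averaging; counts are not pooled).
* Extraction QC: percentage with a Wilson score interval (statsmodels).
* Dose–response: replicates divided by the DMSO-control mean, summarized
  per dose as mean ± SEM. The optional 4-parameter logistic fit exists for
  synthetic-recovery tests only; no curve fit is asserted for real data.
* Secretion rate: (endpoint − baseline)·V/(cells·duration) in the
  well-mixed single-compartment approximation (the same back-calculation
  the published per-cell rates imply); negative rates are flagged as net
  consumption (the SPP-1 case, baseline 5244.72 pg/mL) and never clipped.
  The full PDE inverse problem is intentionally out of scope.

## Synthetic data

Generators mirror the shapes of the real tables with stated noise
conventions: Poisson cells per ROI with Binomial live calls; forward
well-mixed endpoints with unit-mean lognormal noise and twofold-dilution
bookkeeping; Hill-curve viabilities with additive Gaussian noise truncated
to [0, 1]; Bernoulli device outcomes. All are `numpy.random.default_rng`
seed-deterministic and write their ground truth to a sidecar. What passing
recovery tests show is that the estimators invert the stated generative
models at realistic noise levels — not that real chips satisfy those models
(real data carry segmentation errors, plate effects and spatial
correlations the generators do not emulate).

## Problem sizes and defaults

The shipped runs use Δx = 5 µm (700 cells across the half cross-section,
~500 in the Transwell column), 10 s sampling for the 1800 s extraction run
and 300 s sampling for the 24 h secretion run. The extraction scenario
completes in ~2 s and the full two-geometry cytokine comparison in ~2 min
on one CPU.

## Known limitations

* 1-D across-width transport: lengthwise gradients, port geometry and the
  third dimension are lumped into the reservoir conductance.
* The advective path ends at the communication/tumor-gel interface instead
  of resolving the vertical outflow to the ports; volume continuity is not
  enforced inside the 1-D domain during drainage.
* The Transwell membrane is non-hindering; pore transport is not modeled.
* No reaction, uptake, binding or gel-degradation coupling — collagenase
  transport is simulated, its enzymatic action on the gel is not.
* Absolute cytokine concentrations are in arbitrary per-solute units by
  construction; only ratios and arrival times are quantitative.
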