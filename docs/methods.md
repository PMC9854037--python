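# Methods

`brachydose` implements the TG-43/TG-43U1 dosimetric chain for the two
encapsulated ⁶⁰Co source designs of the GZP3 HDR afterloader: a simplified
kerma-scoring photon Monte Carlo that generates the dose data, the inverse
step that turns dose grids into TG-43 parameters, a deterministic fitter for
the radial dose function, and the forward dose-reconstruction engine used
for along–away QA tables. This note records the models, the defaults and the
reasoning behind the genuinely open design choices.

## Source model

Each source is a cylindrical ⁶⁰Co core (radius 0.05 cm; active length
L = 0.1 cm for channels 1 and 2, 0.2 cm for channel 3) centered in a
stainless-steel capsule of 0.21 cm outer diameter and 0.58 cm length. The
vendor materials table gives cobalt at 8.85 g/cm³ (the accompanying text
says 8.9; the explicit materials table wins, and the value is
config-overridable) and two austenitic steels; the capsule uses the
spring-cover/coupling steel, and a cable stub of the wire-rope steel —
2 cm long by default, configurable — is attached to the proximal (−z) end.
The stub is the only structure producing the reduced anisotropy observed at
θ → 180°; its true length is not published. The core is centered axially
(`core_axial_offset = 0`) because the published anisotropy tables are nearly
mirror-symmetric and no offset is documented. The channel-3 capsule
dimensions are likewise not published; the channel-1/2 capsule is reused,
which the near-identical published dose-rate constants (1.116 vs 1.115
cGy h⁻¹ U⁻¹) support. Coordinates: z along the source axis, +z toward the
distal tip, origin at the active-core center, θ measured from +z (θ₀ = 90°
is the transverse plane).

## Photon transport and scoring

The Monte Carlo is analog and photon-only. Each decay emits the two ⁶⁰Co
lines (1.17 and 1.33 MeV, one photon each) from a point sampled uniformly in
the core, with independent isotropic directions. Interactions are

* Compton scattering on free stationary electrons (Klein–Nishina, sampled
  with the standard two-branch composition–rejection scheme; no Doppler
  broadening or binding),
* photoelectric absorption (local energy deposition), and
* pair production as local absorption of E − 1.022 MeV with two 0.511 MeV
  annihilation photons re-emitted back-to-back along an isotropic axis.

Rayleigh scattering is not transported: at the ⁶⁰Co energies it is a
sub-percent, strongly forward process. Consistently, the transport
attenuation coefficient *excludes* the coherent part (see below) — folding
it into an absorptive channel would spuriously kill low-energy scattered
photons and bias the build-up low by ~1%. Photons are terminated below the
10 keV cutoff or on leaving the phantom. Free paths are sampled region by
region with exact distance-to-boundary ray tracing through the nested
cylinders (core / capsule / cable stub); resampling at each boundary is
exact because the exponential free path is memoryless.

There is no electron transport. Collision kerma is scored with a
track-length estimator — track length in cell × E × (μ_en/ρ)(E) / cell
volume — which approximates absorbed dose wherever charged-particle
equilibrium holds (≳0.7 cm from a ⁶⁰Co source); cells below 0.7 cm carry an
explicit kerma-approximation flag and are not used for validation against
published small-r values.

Water geometry: a 30-cm-radius liquid-water sphere acting as an unbounded
phantom, scored on cylindrical rings sized by the three-zone scheme
(0.025 × 0.005 cm for r ≤ 1 cm, 0.05 × 0.05 cm for 1 < r < 3 cm,
0.1 × 0.1 cm for 3 ≤ r ≤ 10 cm). Air geometry: a 3-m cube of dry air
(0% humidity, the vendor-table composition), scored on a 0.1 × 0.1 cm ring
on the transverse axis at 100 cm by default; the air-kerma strength is the
scored kerma rate × d², in U = cGy cm² h⁻¹ (1 Bq = 3600 decays/h). The
scoring distance is not published; 100 cm with d² scaling is the TG-43U1
convention, and an inverse-square invariance test checks 50 vs 100 cm.

Type-A uncertainties come from the variance over 100 equal history batches
(the batching used for the published uncertainties is unstated). A single
seeded generator drives each run; the seed is recorded in every output and
identical seeds reproduce results bit-for-bit.

### Photon coefficients

Cross sections are shipped as package data (`data/xs/*.csv`): μ/ρ, μ_en/ρ
and per-interaction fractions on a 20-point log grid, 10 keV–2 MeV,
log-log interpolated. For water and air, μ_en/ρ are standard published
compound values. The Compton channel is the closed-form Klein–Nishina cross
section times the electron density Z/A; the photoelectric channel is
recovered as μ_en/ρ minus the Klein–Nishina energy-transfer term (exact for
low-Z media where fluorescence and radiative corrections are negligible in
the energies that matter); their sum is the coherent-free transport
attenuation. For the steels and cobalt, the photoelectric part is anchored
on the published iron curve and scaled by Z^4.7/A — the metals only
attenuate (the capsule is 0.055 cm of steel transversally), so percent-level
accuracy there moves the final results by well under 0.1%. The pair channel
uses a near-threshold cubic that is negligible (<10⁻⁴ of interactions)
below 1.33 MeV. Mixtures follow mass-fraction additivity over the vendor
compositions.

These embedded tables stand in for the EPDL97/XCOM libraries used by
general-purpose codes; replicating those libraries is out of scope.

## TG-43 extraction and engine

The engine implements Ḋ(r,θ) = S_k Λ [G(r,θ)/G(r₀,θ₀)] g(r) F(r,θ) with
(r₀,θ₀) = (1 cm, 90°). The line-source geometry factor β/(L r sinθ) computes
β as the difference of the two endpoint arctangents (stable at small θ and
large r), with the degenerate limit 1/(r² − L²/4) on the axis and 1/r² for
L = 0. g interpolates linearly in r, F bilinearly in (r,θ) with θ clamped
outside the tabulated range; node-exactness is the contract (log-r
interpolation was rejected: g and F vary slowly). Outside the tabulated
radial range the engine errors by default; the QA-table generator instead
marks such cells missing.

Extraction inverts the same equations on a scored grid. Two numerical
choices matter:

* A tabulated θ = 0 (or 180°) sample refers to a ring cell of zero radius;
  the geometry factor for such samples is evaluated at 0.5° (configurable)
  off the axis. G itself has a finite on-axis formula, but the scored
  quantity does not live on the axis.
* The 1D anisotropy φ_an(r) = ∫Ḋ sinθ dθ / (2Ḋ(r,θ₀)) is evaluated by
  composite trapezoid on the available angles, with the profile extended to
  0°/180° by clamping F to its last tabulated value (the sinθ weight makes
  these tails sub-0.3%). The quadrature is normalized by the trapezoid of
  sinθ on the same grid rather than by the exact 2: this makes an isotropic
  profile integrate to exactly 1 on any grid (the definition's
  normalization) and cancels the O(Δθ²) discretization of the sine weight,
  which on the published 10° grid is a 0.6% effect.

Even so, integrating the *published* F columns gives φ_an values ~0.4–0.7%
below the published φ_an row at every radius — the printed row was evidently
computed from unrounded internal profiles. The packaged tables are stored
verbatim; isolated outliers (e.g. the channel-3 F entries 1.331/1.332 at
r = 2 cm, and several along–away cells) are flagged, never altered, by a
neighbour-deviation rule (>25% from every adjacent finite cell). The
published along–away tables additionally carry a near-uniform factor ≈3.4
relative to a TG-43 reconstruction at S_k = 1 U, so they are shape-only
references, not numeric targets.

Cross-table comparison statistics support both denominator conventions
((B−A)/A and (B−A)/B), matching the two conventions used for cross-code and
cross-source comparisons. The uncertainty budget is a plain root-sum-square
of percent components (types A and B), reported to two decimals.

## Radial dose function fit

g(r) is fitted to (a0 r⁻² + a1 r⁻¹ + a2 + a3 r + a4 r²)e^(−a5 r) over
0.25–10 cm by profiling the one nonlinear parameter: a grid scan of a5 over
[0, 1] cm⁻¹ (step 0.01) with a linear least-squares solve for a0–a4 at each
value, followed by bounded scalar refinement — deterministic, reproducible
bit-for-bit, and immune to local minima. The fit is unweighted; since
g ∈ [0.85, 1.04], weighting by 1/g² changes nothing material.

On the published channel-1/2 table this gives R² = 0.9948 and a maximum
relative deviation of 0.71% (channel 3: 0.9967, 0.52%). The published claims
(R² = 0.995, deviations <0.46%/<0.41%) cannot be reproduced from the printed
data: a linear-programming Chebyshev fit shows the *best possible* maximum
deviation of this model over the 14 printed channel-1/2 points is 0.53%, and
the published coefficients themselves evaluate to 0.746 at r = 1 cm, where
g(1) ≡ 1. Fit quality, not coefficient equality, is therefore the package's
comparison surface, and the residual gap is reported as-is.

## What the simulator does and does not emulate

The built-in Monte Carlo reproduces the study design — source geometry,
two-line spectrum, phantoms, scoring scheme, per-decay normalization — with
simplified physics (no electron transport, no Rayleigh, free-electron
Compton, compact coefficient tables) and desk-scale statistics. At 10⁷
decays (the default used by the acceptance script and tests; minutes on one
CPU, vs 5 × 10⁹ histories at study scale) the reference-point dose carries
~0.4% and the air-kerma strength ~1% type-A uncertainty. Validation against
the published dose-rate constants and air-kerma strength uses a ±2% band
that budgets simplified physics plus this sampling error; observed
agreement at the default seed is −0.9% (Λ, channels 1&2), −1.7% (Λ, channel
3, the larger self-absorbing core being the harder case) and −0.2% (S_k).
Passing these checks shows the chain source→transport→scoring→extraction is
consistent at the percent level; it does not certify the package for
clinical dosimetry, nor does it validate the sub-0.7-cm region, the β/δ-ray
contribution (excluded, as the capsule absorbs it), or tissue
heterogeneities.

## Degenerate inputs and tie-breaks

Scoring cells with zero track length yield missing (never zero) extracted
values; the extraction requires a scored reference cell at (1 cm, 90°) and
θ coverage reaching 5° and 175° for φ_an. The fitter requires ≥7 points
(6 free parameters) and positive g. Ring cells whose inner radius would be
negative (θ near the axis) clamp to discs. If the a5 refinement step does
not improve the gridded optimum, the grid value wins (both are
deterministic).
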