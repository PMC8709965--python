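# Methods

This note records the models behind each stage of the chain, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Phantoms and materials

Materials are elemental weight-fraction compositions (H, C, N, O plus a
lumped `other` for trace elements) with bulk densities: water 1.00,
brain 1.04, skin 1.09, soft tissue 1.00, cortical-bone class 1.85,
PMMA 1.19 g/cm³, air 1.205 mg/cm³. Compositions are validated to sum to
1 within 1e-3.

The water QA tank is 21 × 21 cm in cross section and 28 cm deep with
1 cm acrylic walls and a 2 mm entrance window; the wall material is a
design choice (PMMA is the usual tank plastic) and its effect is small
because the walls are thin. Grid convention: 0-based indices, voxel
centres as positions, beam along +z with the entrance window at z = 0
and the beam axis through x = y = 0.

The head phantom is a concentric sphere, *not* an anatomical model: a
3 mm skin shell, a skull shell, a brain shell and a soft-tissue core,
with a 1 cm diameter tumour sphere centred 4 cm below the skin surface
on the beam axis (beam enters the vertex). The outer radius (80 mm),
skull thickness (7 mm) and brain-shell thickness (45 mm) are free
parameters of the stand-in, chosen as plausible magnitudes; nothing
downstream depends on their exact values. ROI masks (tumour, brain
excluding tumour, skin) are pairwise disjoint by construction.

Boron loading stores the *blood* concentration (default 25 µg/g) in
every non-air voxel; the tumour-to-blood ratio is applied at the
weighting stage, not in the phantom. This split is what makes the
weighted-dose recombination reproduce the published three-system totals
(see below).

## Beam model

The accelerator target and beam-shaping assembly are out of scope; the
source is a parametric planar disk (10/12/15 cm clinical collimator
diameters, treated as perfect apertures). The spectrum is built from
three band fractions: a 293 K Maxwellian thermal component, a 1/E
epithermal component, and an exponential fast tail (scale 1 MeV),
discretized onto the group structure. Defaults are epithermal-dominant
(0.05/0.85/0.10) with 3% photon contamination — representative of an
epithermal BNCT beam, not a fit to any measured spectrum. Angular
distribution: 51 equal-cosine bins on [0, 1] weighted by cos²θ
(forward-peaked); the bin count is the convention for binned planar
sources, the cos² shape is a design choice. Within a group, energies are
sampled log-uniformly, which is exactly the 1/E density — so the
epithermal component is continuous 1/E, and the closed-form mean
(E₂ − E₁)/ln(E₂/E₁) is a testable property.

## Energy groups

Five neutron groups with boundaries (MeV)
1e-20, 2.53e-8, 5.3e-7, 4e-2, 1, 30. The 0.53 eV and 40 keV edges are
the thermal/epithermal and epithermal/fast reporting limits (upper
bounds inclusive), so band reporting is a partition of groups; the kT
split at 2.53e-8 MeV resolves 1/v behaviour inside the thermal band.
Representative energies (geometric midpoints, kT/2 for the lowest
group) evaluate the 1/v cross sections.

## Cross sections

Embedded constants, not an evaluated library: 2200 m/s microscopic
absorption (¹⁰B 3837 b, ¹⁴N(n,p) 1.83 b, H(n,γ) 0.332 b) scaled 1/v to
each group's representative energy, and representative elemental elastic
scattering magnitudes per group (thermal H raised toward its bound value
so hydrogenous moderation is not badly underestimated). Group transfer is
an adjacent-group downscatter model: the probability of leaving group g
per scatter is ξ/Δu(g) with ξ the material's mean logarithmic energy
decrement and Δu the group lethargy width; the lowest group scatters
in-group and there is no upscatter. This free-gas simplification replaces
bound thermal-scattering-law physics — a documented limitation: water
thermalization is qualitatively right (sub-surface thermal build-up,
tested as a shape property) but depth curves are not quantitative and
are never asserted against measured or published profiles.

## Transport

Woodcock (delta) tracking against a per-group majorant removes all
voxel-surface geometry code: flights are sampled from the majorant,
collisions accepted as real with probability Σ_t(voxel)/Σ_maj. Real
collisions absorb (terminating the history) or scatter isotropically
with group transfer; absorptions in hydrogen emit a 2.22 MeV capture
photon with probability Σ_Hγ/Σ_a of the voxel (boron dilutes it; the
478 keV boron-capture line is neglected). Photons are transported with
attenuation-only physics (single energy, per-material μ) — the photon
*spatial distribution* is what the gamma dose needs at desk scale, not a
full coupled cascade.

Flux is scored with the collision-at-majorant estimator: a score of
1/Σ_maj at every real or virtual collision, the standard unbiased
estimator of track-length flux under delta tracking. The majorant is
floored at 0.5 per minimum-voxel-width so the estimator stays defined
(and adequately dense) in air and void; extra virtual collisions are
physically inert. Statistics are batch-based (default 10 batches); the
relative error of a tally is sd(batch means)/(grand mean · √n), with
zero-mean entries flagged NaN rather than silently zero. Particle
balance (launched = absorbed + leaked) is exact per run and asserted in
tests; identical seeds give bit-identical tallies.

Validation is analytic, by construction of special cases: a one-group
pure absorber against the Beer–Lambert closed form in absolute
normalization (per-slab track length over voxel volume); a void grid
(everything leaks, flat beam-column fluence); a uniform volumetric
source in a deep absorber against the one-group balance ∫φ dV = 1/Σ_a.

## Dosimetry and weighting

Flux-to-kerma coefficients (Gy·cm²) per material, group and channel:
boron as σ(E)·E_αLi per ¹⁰B atom (2.33 MeV deposited locally, per µg/g),
nitrogen as σ(E)·0.626 MeV per ¹⁴N atom, hydrogen as elastic recoil with
mean transfer E/2, photons as μ_en/ρ · E at the 2.22 MeV line. The 1/v
channels scale as √(E_ref/E) across thermal groups by construction
(asserted to 1e-6). Doses are per source particle; a `source_strength`
scalar scales to a delivered irradiation, since absolute beam output is
configuration, not physics.

The weighted dose is D_w = CBE·(T:B)·D_B + RBE_N·D_N + RBE_H·D_H +
RBE_γ·D_γ per voxel with that voxel's tissue parameters: tumour
(3.8, 2.9, 2.4, 1, T:B 3.5), skin (2.5, …, 1), brain and soft tissue
(1.34, …, 1), bone (1, …, 1), water (1, RBE_N 0, 2.4, 1, 1), air all
zero. Applying T:B at the weighting stage on blood-level boron exactly
reproduces the published brain totals of all three benchmark systems
(4.5/4.2/4.2 Gy_w) and the SERA tumour total (67.9 Gy_w) from their
printed component doses; the remaining tumour and skin cells miss by up
to ~0.9 Gy_w, consistent with one-decimal rounding of the printed
components amplified by the CBE·T:B = 13.3 boron factor, so only the
exactly-recombining cells are asserted.

## Gamma index

For each reference voxel above the dose threshold (default 10% of the
reference maximum), γ is the minimum over evaluated positions of
√[(Δr/DTA)² + (ΔD/δD)²]. Conventions, chosen where practice varies and
flagged as such: global normalization to the reference maximum by
default (local mode available); search radius 2·DTA on a trilinear
subvoxel lattice of step DTA/10; γ = 1 counts as a pass; sub-threshold
voxels are excluded from both the map and the pass-rate denominator.
The search processes lattice offsets in shells of increasing distance
and drops a voxel once its running minimum beats the pure distance term
— an exact early termination, verified against an exhaustive
brute-force lattice minimization (independent interpolation code) to
1e-6 on random grids. Pass rates are monotone under relaxation of either
criterion, and a pure rigid shift of a steep-gradient field fails/passes
across the DTA = shift boundary, both asserted.

## Activation analysis

The reaction rate per atom per coulomb inverts a decay-corrected peak
count for a segmented irradiation (charge Q_i over duration Δt_i):
build-up factor Σ (Q_i/Δt_i)(1 − e^(−λΔt_i)) e^(−λτ_i) with τ_i the
total duration of subsequent intervals — the printed equal-interval
exponent (n − i)Δt is recovered exactly when all Δt are equal, and the
generalization handles unequal ones. The closed form is validated
against an independent fixed-step RK4 integration of
dN/dt = R·n·q(t) − λN followed by count accumulation, agreeing to far
better than 0.1% over randomized histories. Cadmium difference:
φ_th = (R_bare − R_Cd)/σ_eff with σ_eff defaulting to the 2200 m/s gold
value 98.7 b times a Westcott g ≈ 1.005 (the convention is stated
because measurement reports often leave it implicit). No self-shielding
or cadmium-cutoff corrections are applied. Wire profiles normalize
per-segment rates by segment mass and carry √C/C Poisson uncertainties.

## Synthetic data

The counting generator forward-evaluates the same build-up/decay/
counting kinetics the closed form inverts (shared implementation — the
round trip with Poisson off is exact by design and tested to machine
precision; the ODE oracle is the *independent* check) and
Poisson-samples the expected counts. It does not emulate detector
resolution, dead time or background continua, so recovered-rate spreads
reflect counting statistics only. Dose-grid perturbations apply a
systematic scale, a rigid trilinear-resampled shift and voxelwise
Gaussian noise, in that order, with a recorded seed. The depth-dose
fixture is e^(−μz)(1 − e^(−kz)) axially (k solved by bisection so the
maximum sits exactly at the requested build-up depth; this requires
μ·z_build < 1) times a sigmoidal flat-top transverse profile.

Because every generator is parametric and smooth, passing tests show the
*chain* is self-consistent and agrees with its analytic oracles; they do
not show agreement with a real accelerator beam, real CT anatomy, or
measured depth curves, all of which depend on beam-model physics that is
out of scope here.

## Problem sizes and defaults

Default study sizes are chosen so each driver runs in seconds: water QA
at 10 mm voxels with 6e4 histories over three fields; the head plan at
3 mm voxels (the skin shell needs ≤ 3 mm) with 4e4 histories; the
transport benchmark at 1e5 histories / 10 batches; gamma sweeps on
30×30×45 grids at 2 mm spacing; 50 randomized activation histories and
100 Poisson replicates. Monte Carlo assertions use 3 batch standard
errors (2 for the mean-recovery check, which is the conventional
parameter-recovery bound); statistical sampling tests use 4–4.5 σ
binomial bounds so they are stable under seed changes.

## Known limitations

Free-gas adjacent-group downscatter (no S(α,β), no upscatter);
attenuation-only photons; few-group embedded cross sections; perfect
collimator aperture (no penumbra physics from the collimator material);
no CT-derived anatomy; no DVH beyond mean/max/volume; no HPGe spectrum
fitting. Each is a deliberate scope boundary of a desk-scale check, and
none affects the parts validated analytically.
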