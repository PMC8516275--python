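# Methods

`osteodose` computes dose factors for active (red) bone marrow exposed to
bone-seeking beta emitters — ⁸⁹Sr and ⁹⁰Sr with its equilibrium daughter ⁹⁰Y —
using stochastic parametric voxel phantoms of skeletal spongiosa. This note
documents the model, its parameters, the numerical choices, and the limits of
what the test suite demonstrates.

## The dosimetry problem

Strontium is incorporated uniformly into bone mineral. The two source regions
are the trabecular bone volume (TBV) and the cortical bone volume (CBV); the
target is the marrow filling the intertrabecular cavities. Active and
inactive marrow are assumed to receive equal doses, so the marrow-cavity
tally applies to AM without a cellularity correction. The quantity of
interest is the dose factor

    DF(AM←S) = dose rate in marrow per unit activity concentration in S,

reported in units of 10⁻¹⁴ Gy s⁻¹ per Bq kg⁻¹. For a voxel phantom with
source mass `m_S` and marrow mass `m_AM`,

    DF = n_e · ē_AM · 1.602×10⁻¹³ J/MeV · m_S / m_AM,

where `ē_AM` is the mean energy deposited in marrow per source electron
(Monte Carlo tally) and `n_e` the number of beta electrons per parent decay
(2 for ⁹⁰Sr+⁹⁰Y in secular equilibrium, both betas scored per parent decay —
"per Bq/kg" refers to parent ⁹⁰Sr activity).

Mean beta energies are near 0.6 MeV, so electrons travel ~2 mm in spongiosa:
far enough that individual trabeculae are penetrable and microstructure
enters only statistically, but short enough that segment size and the
cortical shell control escape. Both scales must therefore be modeled.

## Anatomical model

A hematopoietic site is divided into stylized segments: round cylinders
(RC: height h, diameter d₁), elliptical cylinders (EC: h, axes d₁ × d₂) and
"deformed" cylinders (DC) whose cross-section blends linearly along the axis
from a circle d₁ to an ellipse d₂ × d₃ (the blend profile is a design choice;
only the end cross-sections are constrained by the source data). A cortical
shell of thickness Ct.Th covers the outer walls; faces where two modeled
segments touch carry no cortex. Whether an axial face is "outer" follows
from the segment adjacency encoded per segment in the registry.

The shipped registry covers the femur for six age groups (newborn, 1 y, 5 y,
10 y, 15 y, adult), with sex-specific dimensions from 15 y on. Growth is
taken as complete at 15 y, so the adult rows reuse the 15-y macro-dimensions.
The registry is a set of YAML files; other sites can be added without code
changes.

Each parameter carries an inter-individual CV (%). Randomized individuals
are drawn per parameter from truncated normals (±3 SD, floored at 10% of the
mean); a drawn cortical thickness is clamped below 90% of the smallest drawn
cross-section semi-axis to keep the geometry realizable. BV/TV, tabulated as
mean plus range, is drawn from a truncated normal with SD = (max − min)/4
confined to [min, max]. Sampling is a pure function of (spec, seed).

Materials: hydrated mineralized bone (newborn 1.65 g/cm³, adult 1.90 g/cm³ —
a representative value for the adult measurement series; ages past the first
year use adult values, with no interpolation) and active marrow
(1.029 g/cm³), with 10-element mass-fraction compositions. Spongiosa
mixtures for homogeneous-medium calculations combine bone and marrow by
volume fraction.

## Spongiosa generator

Spongiosa is modeled as a deformed simple-cubic lattice of rod-like
trabeculae. Nodes sit on a cubic grid of spacing `s·Tb.Sp`, each jittered
uniformly per coordinate by ±(intra-specimen CV of Tb.Sp, default 25%) of
the spacing, and each carries a lognormal thickness with mean Tb.Th and the
intra-specimen CV of thickness (default 25%; within-specimen histomorphometry
distributions are broad and near-lognormal). Every nearest-neighbour edge is
a conical frustum between its end-node half-thickness spheres; membership of
a point is distance-to-clamped-axis within the linearly interpolated radius,
which makes the junction spheres implicit. Rods disconnected by later
clipping are retained as bone.

A cubic rod lattice at the literature Tb.Th/Tb.Sp ratio does not reproduce
the literature BV/TV, so the generated spacing is calibrated: a bisection on
the spacing scale `s` (volume fraction is strictly decreasing in `s`)
brackets the target on a small 12³-cell generation box, then the scale is
refined against the BV/TV of the voxelized, cortex-capped segment itself
using the leading VF ∝ 1/s² scaling — i.e. the model is calibrated to fit
the input parameters *after* voxelization. The refinement converges in one
or two extra voxelizations and leaves the measured BV/TV within 0.5%
(default tolerance) of the target.

## Voxelization and morphometry

A voxel belongs to a structure according to its centre point: trabecular
bone if inside both the segment shape and a rod, marrow if inside the shape
only, void outside. The default voxel edge is Tb.Th/2 clamped to 70–160 μm;
adult femur phantoms in the shipped analyses use 140 μm (one voxel per adult
trabecula, inside the same span), which keeps the largest grid
(trochanter area, ~470×470×300) tractable. Cortex capping converts every
in-shape voxel within Ct.Th of a capped face (lateral boundary offset by
Ct.Th; axial slices within Ct.Th of a capped end); as a result some
trabeculae contact the cortex and others do not, as in real metaphyses.

Morphometry is read directly off the voxel counts: volumes are counts ×
voxel volume, masses use registry densities, BV/TV = TBV/(TBV + marrow)
voxels. Mean trabecular thickness is estimated by the rod-model relation
d = 4V/S with the face-counted voxel surface corrected by 2/3 for staircase
bias — a reported diagnostic, not an input. Linear dimensions are measured
as occupied-index extents, which are unbiased for a shape at random grid
offset.

Generated-phantom fidelity (the acceptance ensemble): 12 randomized + 1
population-mean phantom per segment; the ensemble-mean measured BV/TV and
extents agree with the ensemble-mean inputs to well under 1%.

## Beta spectra

⁸⁹Sr, ⁹⁰Sr and ⁹⁰Y are all unique first-forbidden ground-state transitions.
Spectra are built from Fermi theory: phase space p·W·(W₀−W)², the screened
non-relativistic Fermi function 2πη/(1−e^(−2πη)) with η = αZ_daughter·W/p,
and the unique first-forbidden shape factor p² + q². Endpoints are the
standard decay-data values 1495.1 keV (⁸⁹Sr), 546.0 keV (⁹⁰Sr), 2280.1 keV
(⁹⁰Y). The combined ⁹⁰Sr+⁹⁰Y spectrum is the per-electron average of the two
branches with emission multiplicity 2 recorded. Computed means: 0.607 MeV
(⁸⁹Sr) and 0.587 MeV (⁹⁰Sr+⁹⁰Y per electron), both close to 0.6 MeV. A
tabulated-spectrum override hook accepts (energy, intensity) tables for
callers who prefer evaluated spectra. Energies are sampled by inverse CDF on
a 1 keV grid; source positions are uniform over the region's voxels and
within each voxel, with isotropic directions.

## Electron transport

Condensed-history, analog (unweighted), single-threaded and seeded:

* Collision stopping power: Bethe formula for electrons with the Møller
  closure term, Bragg-additivity ⟨Z/A⟩ and mean excitation energy over the
  elemental mass fractions (standard I values per element). No
  density-effect correction — below 3 MeV in light media it is a
  few-percent effect at most.
* Radiative stopping power: the Z̄·E/800 rule relative to the collision
  term. Bremsstrahlung photons are *not* transported: radiative losses are
  scored to a separate channel and treated as leaving the system. The yield
  is ≲1% of emitted energy for these spectra.
* Stepping: step length is the smaller of (max fractional energy loss,
  default 5%) and the distance to the next voxel face (exact ray marching);
  the stopping power is re-evaluated at the midpoint energy. Energy loss
  within a step is deterministic (continuous slowing down); no delta-ray
  production or energy-loss straggling.
* Scattering: after each step the direction is deflected by a Gaussian
  multiple-scattering angle of Highland width (radiation lengths by mixture
  rule; the logarithmic correction clamped at 0.25, width capped at 1.4 rad).
* Termination: below the cutoff (default 10 keV, residual range ≪ one voxel)
  the remaining energy is deposited locally. Void voxels and the grid
  exterior are vacuum — the segment sits in vacuum by scope, so backscatter
  from surrounding tissue is neglected.

Per-history energy conservation (deposits + escaped + radiative = E₀) holds
to 10⁻⁶ relative and is asserted in the tests. Tallies report per-electron
means with batch standard errors (default 20 batches).

Default statistics: 2×10⁵ histories per segment and source region, targeting
sub-1% MC standard error on the marrow tally; the shipped acceptance
analyses use 10⁵, which keeps MC error near 1% — negligible against the
±25% comparison band and the ~15% individual variability.

## Aggregation and uncertainty

Segment DFs combine to a site average weighted by segment marrow volume (the
AM fraction per unit marrow volume is taken equal across a site's segments),
and site DFs combine to a skeletal average weighted by the age-dependent AM
distribution (renormalized; sites absent from the input are dropped with
renormalization and logged). Individual variability is the relative RMSD of
an ensemble of randomized-phantom DFs about the basic-phantom DF (default
ensemble: 12 supplementary + 1 basic, matching-ensemble CVs at segment and
site level). MC standard errors and individual-variability CVs are always
reported separately.

## What the shipped analyses show — and what they do not

The acceptance computations reproduce the published femoral anchors: BV/TV
and dimension fidelity < 1%, spectrum means ≈ 0.6 MeV, CSDA path ≈ 1.9 mm
and full 10-mm containment of absorbed energy in homogeneous spongiosa, and
site-average DF(AM←TBV) of ≈ 7.0 (newborn) and ≈ 3.3 (adult male) and
newborn-diaphysis DF(AM←CBV) ≈ 6.7 against printed values of 6.8, 3.1 and
6.9 — agreement within ~10%, inside the ±25% band that covers the documented
physics simplifications (no photon transport, Gaussian multiple scattering,
no delta rays, no straggling).

The 10-mm containment is defined over absorbed (collision) energy; measured
over emitted energy it is ~98.7% only because the ~0.9% radiative channel is
untransported by design.

Not reproducible at this scale and out of scope: skeletal-averaged DFs and
the full uncertainty budget (they require the parameter sets of all
hematopoietic sites, which the curated registry does not ship); the
strontium biokinetic model; bone endosteum as a target; photon emitters.
The rod-lattice generator is compatible with, but not identical to, the
original generator: the exact node-perturbation law and junction-radius rule
of that software are unpublished, so the uniform jitter and lognormal
thickness here are this package's own documented choices, validated through
the BV/TV calibration and the fidelity ensemble rather than by construction.
The aggregated AM-distribution table entries for sites whose source rows
split over bone parts are best-effort totals; only the skeletal-averaging
machinery consumes them.
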