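# Methods

## The modelling problem

Deep brain stimulation in rodents targets nuclei (the subthalamic nucleus,
STN, and the entopeduncular nucleus, EPN — the rodent homologue of the globus
pallidus internus) that are small compared with the electrodes available, so
leads are implanted *cranial to* the target rather than inside it.  The field
then spreads through the thalamus and the internal capsule above the target,
risking off-target stimulation.  This package asks the design question
quantitatively: for four bipolar lead geometries, what fraction of the
predicted neural activation lands in the target nucleus?

The pipeline has five stages, each its own module:

1. **phantom** — a synthetic labelled tissue volume with anisotropy;
2. **dielectrics** — frequency-dependent complex admittivity per tissue;
3. **electrodes** — parametric lead geometry and placement;
4. **solver** — the electro-quasistatic finite-element solve;
5. **spectrum** + **activation** — Fourier synthesis of time-domain fields
   and threshold-based activation bookkeeping,

orchestrated by **pipeline**.

## Volume conductor model

The electric potential obeys the electro-quasistatic (EQS) equation

    div[ (sigma(r, w) + j w eps(r, w)) grad phi(r) ] = 0,

with Dirichlet values on the two exposed electrode contacts and zero normal
current on every other boundary.  Stimulation is current-controlled: the
solution for arbitrary contact potentials (+-0.5 V seeds) is rescaled by
linearity so the core-contact current matches the prescribed value — here the
complex Fourier coefficient of a 60 us, 60 uA rectangular pulse train.

Assumptions inherited from the EQS approximation: no magnetic induction, no
wave propagation, linear tissue response.  The electrode-electrolyte double
layer is not modelled (its effect on current-controlled stimulation is a
series impedance that the current rescaling absorbs), so computed contact
impedances would not be physical and are not reported.

## Synthetic phantom

No atlas or diffusion-imaging data ship with the package; the phantom module
generates a parametric stand-in that preserves the topology that drives the
design comparison:

* gray-matter background with a CSF rind (0.25 mm) at the domain boundary;
* an **oblate STN-analogue** ellipsoid (semi-axes 0.9 x 0.7 x 0.30 mm,
  ~0.79 mm^3, lateral extent well above dorsoventral — the rat STN is a
  flattened lens of roughly this volume);
* a **compact EPN-analogue** (0.42 x 0.42 x 0.38 mm, ~0.28 mm^3);
* a thalamus slab dorsal to both targets, through which the shaft passes;
* an internal-capsule-like white-matter sheet between the EPN-analogue and
  the thalamus, with fibres oriented mediolaterally;
* a 0.1 mm encapsulation layer carved around the implanted shaft
  (dielectrically identical to gray matter; carved voxels leave the region
  masks, since scar tissue is no longer nucleus).

Default voxel size is 0.025 mm so the encapsulation shell is resolved by four
voxels.  Coordinates are right-handed millimetres, dorsoventral = +z,
insertion along -z; voxel centres sit at `origin + (i + 0.5) * voxel`.

White-matter anisotropy uses volume-normalised tensor mapping: a prolate
tensor with the fibre direction as principal eigenvector, eigenvalue ratio
set by a fractional-anisotropy level (default FA = 0.7, typical for the
internal capsule, giving a ~3.9:1 conductivity ratio), normalised to unit
determinant so that multiplying by the scalar tissue conductivity preserves
the geometric-mean conductivity.  Anisotropy is applied to white matter only
by default (the tissue classes are configurable); gray matter and CSF stay
isotropic.

**What the phantom does not emulate:** real anatomical shape detail, the
cortical surface, partial-volume mixtures at region boundaries, spatially
varying FA, and the actual atlas geometry around each nucleus.  Passing the
structural tests therefore shows that the *method* ranks the designs as the
anatomy-driven study does under the same topology — not that the absolute
share percentages transfer to a real rat brain.

## Dielectric model

Tissue dispersion uses the standard four-term Cole-Cole parameterisation of
gray and white matter for the *shape* of sigma(f) and eps(f); the
conductivity curve is rescaled to pass through a 50 kHz anchor.  The shipped
anchors — GM 0.25 S/m, WM 0.15 S/m — are editable implementation defaults
(the literature values they stand in for are averages that are not printed
anywhere recoverable), so absolute field magnitudes carry that uncertainty;
design *rankings* are insensitive to a common scale factor because all
designs share the same media.  CSF is a frequency-independent 2 S/m
conductor.  The encapsulation class reuses the gray-matter tables verbatim.
Tables are interpolated log-frequency-linearly; f = 0 returns the pure real
low-frequency conductivity; frequencies above the table clamp with a warning.

## Discretisation and solver

The domain is meshed with trilinear hexahedral elements on a tensor-product
grid graded towards the contacts (target edge length
`min(0.05 mm, core_diameter/6)` at the contacts, growing by a bounded factor
to 0.35 mm in the far field).  The electrode is *embedded*: elements inside
the lead are insulator material (1e-8 S/m), metal contact regions contribute
Dirichlet node sets, and each tissue element carries the phantom label and
anisotropy tensor sampled at its centroid.  An embedded staircase surface has
an effective-radius bias of half a cell; the analytic-oracle configurations
centre their spherical contacts by extending the node predicate half a cell,
which removes the bias from the verification problems (electrode geometry in
study runs is resolved by 3-6 cells across each contact and enters all
designs alike).

Each harmonic solve assembles the complex stiffness matrix (2x2x2 Gauss
quadrature, per-element admittivity times the unit-determinant structure
tensor) and solves the Dirichlet-reduced system to a relative residual of
1e-9 or better.  Small systems (< 6000 unknowns) factorize directly.  Large
systems use a geometric multigrid preconditioner built on the tensor-product
structure — Kronecker-product linear prolongations between every-other-line
node sets, Galerkin coarse operators, Chebyshev(3) smoothing with a
power-iteration spectral bound, direct coarsest solve — inside CG (real, DC)
or BiCGSTAB (complex).  Typical study meshes (~150k nodes) solve in a few
seconds per frequency.

Contact currents come from the consistent (stiffness-residual) flux at the
Dirichlet nodes, which balances between the contacts to solver precision and
is what current rescaling uses.  An independent surface-integral current —
the flux of kappa grad(phi) through a closed box enclosing the contact —
provides the discretisation-sensitive conservation diagnostic; its
core/outer imbalance shrinks monotonically under refinement in the bipole
oracle (2.7e-3 to 5.7e-7 across two refinements at the tested resolutions).

## Fourier FEM and octave bands

The rectangular pulse train's Fourier-series coefficients are evaluated in
closed form (c_k = A w f_rep sinc(k f_rep w) e^{-j pi k f_rep w}); harmonics
are retained up to 1 MHz, above which the 60 us pulse carries negligible
energy.  The repetition rate is not a property of the pulse shape the study
fixed; 130 Hz (a standard DBS setting) is the configurable default.

One FEM solve is performed per *octave band* instead of per harmonic: bands
partition the harmonics at edges f_rep * 2^(m/B), each represented by the
member harmonic nearest the band's geometric centre; every member coefficient
reuses the band's transfer field.  For non-dispersive media this reduction is
exact; on a dispersive two-layer toy problem the peak-field error of the
default reduction is ~0.2% against the full per-harmonic computation.  Study
runs use DC + 4 bands (5 solves instead of ~7700), a desk-scale setting under
which the band approximation error is far below the geometric effects being
compared.

Time-domain fields are reconstructed per probe point as
E(t) = Re sum_b T_b(x) g_b(t) with g_b the band's coefficient-weighted
harmonic sum.  Activation metrics use the time-domain **peak** of |E(t)| and
|div E(t)| — thresholds in the source literature are amplitude criteria.  Two
numerical choices control the peak of a truncated Fourier series of a
discontinuous pulse: Lanczos sigma factors suppress the Gibbs overshoot, and
the default sampling grid covers the pulse interior and the inter-pulse
interval while excluding the 3% neighbourhood of the idealized
discontinuities.  In the resistive limit the reconstructed peak then matches
the static field scaled to the pulse amplitude to 0.25%.

## Activation estimation

Fields are probed on a regular 0.05 mm lattice within 2 mm of the core
contact centre, excluding points inside the electrode.  Two estimators are
thresholded (strictly: value > threshold):

* |E| > 0.323 V/mm — field-magnitude criterion;
* |div E| > 0.309 V/mm^2 — direction-free surrogate of the activating
  function, computed from the lattice field by second-order central finite
  differences (one-sided at the lattice boundary).  First-order elements have
  no interior second derivatives, so the lattice operator is the well-defined
  place to differentiate.

Both thresholds are median axon-model values for 2.5 um axons from the
source literature.  Activated volume is the supra-threshold point count times
(0.05 mm)^3; each point is attributed to the region of its nearest phantom
voxel; the performance measure is the percentage share of activated volume
inside the target.  Totals are clipped to the 2 mm probe ball (the metrics
exist only there), points in the encapsulation layer are counted in totals,
and a run with no activated points reports an undefined (NaN) share with a
warning.

## Electrode designs

All four designs are axisymmetric concentric bipolar leads (0.5 mm shaft,
0.240 mm platinum/iridium core within the manufacturable 0.125-0.250 mm
range), described by a radial profile and exposed-surface spans:

| design | tip | core contact | outer contact |
|---|---|---|---|
| SNEX100 | sharp cone | cone surface, 0.25 mm | ring 0.75-1.25 mm above apex |
| CEAX100 | sharp cone | cone surface, 0.20 mm | ring 0.65-1.00 mm (closer spacing) |
| SPHERICAL | hemisphere (core radius) | full hemisphere | ring 2.2-2.7 mm (upper shaft) |
| BLUNT | flat disc | bottom disc only; lateral insulating taper | ring 2.2-2.7 mm (upper shaft) |

Exact manufacturer dimensions are not public, so every dimension is a config
parameter and the defaults make the four designs a parameter study of the
class, not certified replicas.  The blunt design's insulating taper is a
truncated cone over the final 0.5 mm of shaft; the relocated outer contact of
the modified designs sits just above the 2 mm probe ball so its own
activation pocket does not enter the bookkeeping region — the design intent
of moving the return away from the target.  Placement puts the tip apex
0.4 mm dorsal of the target's voxel-mass centroid (offset configurable; 0 is
allowed and documented as damaging placement).

## Verification

Analytic oracles validate each stage independently of the implementation
path they check:

* monopole: probed |E|(r) vs I/(4 pi sigma r^2) (<= 5%), activation radius vs
  sqrt(I/(4 pi sigma E_th)) = 0.272 mm (<= 5%), sphere-capacitance current
  (<= 10%);
* concentric two-shell conductor: potential vs the analytic radial solution
  (<= 5%);
* two-sphere bipole: |E| vs superposed point sources (<= 5%), surface-current
  conservation under refinement (<= 2%, monotone);
* linearity: current doubling exact to solver tolerance, 60 uA rescaling to
  1e-12;
* spectrum: closed-form coefficients vs independent quadrature, exact band
  reduction in the resistive limit, <= 5% on the dispersive toy problem;
* divergence stencil: exact on constant/linear fields, within the O(h^2)
  bound on the analytically sampled monopole field.

Median-over-directions probing is used against the spherically symmetric
oracles to suppress staircase noise at individual points.

## Problem sizes and defaults

Study runs use resolution_control = 1 (0.04 mm edges at the contacts,
~150k nodes per design mesh), DC + 4 bands, and the 81^3-point probe lattice;
a full 4-design x 2-target comparison takes a few minutes on one CPU.  The
oracle meshes are 100k-500k nodes.  Mesh-convergence behaviour is monitored
through the conservation-refinement oracle, which also tracks the probed
reference field across resolutions: it changes by under 2% between the two
finest tested levels (3% is the acceptance bound).

## Known limitations

* Absolute activated volumes inherit the uncertainty of the conductivity
  anchors and of the assumed electrode dimensions; only relative design
  comparisons are robust outputs.
* The staircase electrode embedding resolves contact surfaces to the local
  cell size; very thin contact features (below ~2 cells) would be distorted.
* On the default phantom the divergence-metric EPN share for the blunt
  design falls below its STN share because the white-matter sheet adjacent
  to the EPN-analogue captures divergence-metric activation; the
  field-magnitude metric reproduces the full published ordering.  This is a
  phantom-topology effect worth remembering when editing the phantom
  geometry.
* Monophasic rectangular pulses only; charge-balanced biphasic waveforms and
  stochastic trains are out of scope, as are neuron cable models — the
  estimators are deliberately the simple field criteria.
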