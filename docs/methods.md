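# Methods

## Exciton model

Every dye molecule is reduced to a two-level chromophore: a point
position r⃗_n (Å) and a unit transition-dipole direction d⃗_n.  The
one-exciton Hamiltonian in wavenumbers is H_nn = ν̃_n − δ and
H_nm = J_nm, where the site frequencies ν̃_n are independent Gaussian
draws (static diagonal disorder) and δ is the gas-to-crystal shift of
the aggregated environment.  δ is *subtracted*, so the model monomer
sits at ν̃₀ − δ = 19 148 cm⁻¹, consistent with a red gas-to-crystal
shift and the observed ~19 100 cm⁻¹ monomer band.  δ is applied to all
molecules alike; the model makes no distinction between dissolved and
aggregated sites (a frame containing a single molecule represents a
dissolved monomer).

Couplings use the extended-dipole approximation: charges ±μ/l (in D/Å)
are placed l/2 on either side of the molecular position along d⃗_n, and
J_nm is the signed Coulomb sum over the four inter-molecular charge
pairs, multiplied by α to convert D²/Å³ to cm⁻¹.  Dimensional analysis
fixes the order of magnitude of α: 1 D²/Å³ ≡ 5.034 × 10³ cm⁻¹, so the
default is α = 5.04 × 10³ cm⁻¹ Å³ D⁻².  With an α three orders of
magnitude smaller, nearest-neighbour couplings would be ~10⁻⁴ cm⁻¹ and
no J-band could form at all.  At separations ≳ 10 l the four-charge sum
converges to the point-dipole formula α μ² κ / r³ (verified to 1% at
r = 50 l).  Charge pairs closer than 0.1 Å raise a geometry error;
this is what physically motivates the lattice constants below.

Polarized absorption is a pure weighted-lineshape sum: the oscillator
strengths |Σ_n c_nk (μ d⃗_n · ê)|² of the eigenstates are accumulated on
the wavenumber grid and convolved with a zero-mean Gaussian of width
σ_line = 75 cm⁻¹.  No frequency prefactor multiplies the lineshape; if
an absorbance ∝ ν̃ convention is wanted the output can simply be scaled
by the grid.  Couplings are geometry-only and computed once per frame;
the diagonal is resampled independently for each of the
`n_realizations` disorder realizations (default 1000), and each
realization is diagonalized once and projected onto both polarization
vectors.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| ν̃₀ | monomer frequency | 19 498 | cm⁻¹ |
| σ_site | diagonal disorder width | 231 | cm⁻¹ |
| δ | gas-to-crystal shift | 350 | cm⁻¹ |
| q | extended-dipole charge | 0.34 | e |
| l | charge separation | 7 | Å |
| μ | dipole magnitude, q·l | 11.43 | D |
| α | unit conversion | 5.04 × 10³ | cm⁻¹ Å³ D⁻² |
| σ_line | lineshape width | 75 | cm⁻¹ |
| n_realizations | disorder averages | 1000 | — |

## Dichroism conventions

The tube is assumed perfectly aligned with the flow axis; imperfect
alignment is not modelled.  A_∥ uses the axis as polarization vector and
A_⊥ one fixed perpendicular direction.  Then A_iso = (A_∥ + 2A_⊥)/3
(uniaxial average), LD = A_∥ − A_⊥, and LD_r = LD/A_iso, which is 3 for
perfectly axial dipoles and 0 in the isotropic limit.  Wherever A_iso
falls below 10⁻⁶ of its maximum, LD_r is set to NaN to avoid 0/0.
Band averages are arithmetic means over the grid points inside an
inclusive window, without resampling; the band LD_r is the ratio of the
band means (mean LD over mean A_iso), not the mean of the pointwise
ratio — a `pointwise=True` toggle provides the alternative.  Peak
positions are grid argmaxima with ties broken toward lower wavenumber.

## Geometry and the placeholder lattice

Walls are built as planar lattices (basis vectors in nm, fractional
motif offsets, one in-plane dipole angle) and rolled seamlessly onto a
cylinder: the circumferential coordinate maps to an angle via the sheet
width, so every molecule sits exactly at the wall radius; in-plane
dipole angles become tangent-plane vectors.  Because the chromophore is
inversion-symmetric, each dipole is represented by its axial-nonnegative
direction.  Tube radii default to 3.45 / 6.75 nm (6.9 and 13.5 nm
diameters).

The true wall packing of C8S3 is not parameterised here.  The default
brickwork cell is a placeholder chosen under three constraints:

1. **charge-arm clearance** — a stacking period of 1.1 nm along the
   dipole keeps inter-molecular charges ≥ 4 Å apart (a 0.7 nm stacking
   would put opposite charges of stacked neighbours on top of each
   other, since l = 0.7 nm);
2. **feature-space connectivity** — molecular columns every 1.05 nm
   around the circumference keep the 6-D clustering distance between
   in-wall neighbours below eps = 0.2 for any patch orientation (the
   tangent frame rotates by r·Δθ between columns, and coarse columns
   would fragment even a perfectly coherent patch);
3. **realistic density** — the resulting ~0.87 molecules/nm² matches
   the ~0.9/nm² implied by a 780-molecule outer wall on a 20 nm
   segment.

Dipoles are tilted 85° from the circumferential direction (mostly
axial), which makes the dominant stacking coupling strongly negative:
rolled walls are J-aggregates with an intense red-shifted
parallel-polarized band, and LD_r of a defect-free wall is close to 3.
All constants are configurable; nothing downstream depends on their
specific values, only on these structural properties.

## Synthetic recovery (what it emulates, what it does not)

`generate_patchwork` places outer-wall molecules on lattice sites in
spatially contiguous patches: patch seeds are spread by farthest-point
sampling, regions grow breadth-first on the site adjacency graph, all
molecules of a patch share one uniformly random in-surface angle, and
angles of different patches are independent.  Patch orientational
coherence is defined in the *local surface frame*: the in-surface angles
of a patch are identical, while the 3-D dipole vectors of a curved patch
necessarily fan with the tangent frame.  The dispersion helper therefore
measures 1 − ⟨cos(φ_i − φ_j)⟩ on the in-surface angles.

`simulate_assembly` is an intentionally minimal site model: each step,
empty sites adsorb with a fixed probability; a molecule landing next to
an occupied site joins that patch and adopts its angle; otherwise it
nucleates a new patch with an angle drawn uniformly within
± `nucleation_orientation_spread` of the preferred lattice orientation
(π = fully random, 0 = immediately ordered); and each un-aligned patch
of size s snaps to the preferred orientation with probability
min(1, rate/s) per step, merging with the aligned domain.  Occupancy is
non-decreasing and runs are bit-reproducible from the seed.  The model
deliberately omits energetics, desorption, patch migration, domain-wall
healing and solvent; passing tests therefore show that the *analysis
chain* behaves correctly on data with the assumed statistical structure
(monotone growth, early orientational disorder, late global order), not
that real recovery follows these rules.

## Patch identification

Positions are centred, divided by the largest box dimension and
concatenated with the (hemisphere-mapped) unit dipole components into a
6-D feature space; DBSCAN runs with Euclidean metric, eps = 0.2 and
min_points = 2, read as "at least two points within the sphere,
the point itself included" — the weakest density constraint consistent
with that phrasing, and configurable.  With min_points = 2 a point with
any neighbour is a core point, so there are no border points and the
clustering is exactly the connected components of the eps-graph with
singletons as noise; the test suite checks this equivalence against an
independent sparse-graph implementation.  Hemisphere mapping is applied
before clustering because antiparallel dipole representations of one
physical patch would otherwise split it in two.  Position and
orientation features carry equal weight by default; an orientation
weight factor is exposed.  Periodic images are not considered in
position distances.

## Kinetics

Both rate models share the saturating adsorption OD(t) = od_base +
od_amp (1 − e^(−k_ads t)).  The ordered model takes LD(t) = ld_base +
c_ld · od_amp (1 − e^(−k_ads t)); its LD_r is monotone non-decreasing.
The disordered model is the minimal two-compartment sequential scheme
M → O: with M(t) the adsorbed amount and dO/dt = k_ord (M − O),

    O(t) = od_amp [1 − (k_ord e^(−k_ads t) − k_ads e^(−k_ord t)) / (k_ord − k_ads)],

LD(t) = ld_base + c_ld O(t).  O(0) = O′(0) = 0 (delayed onset),
0 ≤ O ≤ M, both models share the plateau LD_r → c_ld·od_amp/(od_base +
od_amp), and for k_ord ≪ k_ads with a positive LD baseline the LD_r has
an interior minimum — the delayed-ordering signature.  The equal-rate
degeneracy k_ord = k_ads is handled by the analytic limit
od_amp (1 − (1 + kt) e^(−kt)).  This functional form is this package's
own minimal realization of the qualitative behaviours it must
reproduce; richer mechanistic models (nucleation-and-growth, island
growth) are out of scope.

Fitting is joint least squares on the concatenated OD and LD residuals
(equal weights by default, configurable) with `scipy.optimize.
least_squares` under bounds (rates > 0, amplitudes ≥ 0, 0 ≤ c_ld ≤ 3),
deterministic given the starting point; the default start is derived
from the series (baseline, plateau, half-rise time).  A series with no
OD rise leaves the rate unidentifiable; the fit is returned flagged
rather than raising.

## Numerical choices

- Wavenumber grid: [ν̃₀ − 5000, ν̃₀ + 2000] at 2 cm⁻¹ by default; a
  warning is issued if the step exceeds σ_line.
- Sticks are deposited with linear splitting between the two bracketing
  grid points and the accumulated spectrum is convolved once with the
  Gaussian kernel (truncated at 6σ).  This adds at most step²/4 to the
  second moment — < 0.01 % of σ_line at the default step — and makes
  1000-realization averages of multi-hundred-site frames cheap, since
  the per-realization cost is one eigendecomposition.
- Units: Å internally in frames, nm at the geometry API; the conversion
  factor is exactly 10.  1 e·Å = 4.8032 D.
- Seeds: every stochastic routine takes an explicit integer seed or
  Generator; the pipeline spawns per-stage seeds from one global seed
  via `SeedSequence` and records them in the manifest.  Frames of a
  time series receive independent spawned disorder streams.

## Problem sizes

Tests and the acceptance script run on scaled geometries chosen for
desk-scale runtime: 6 nm tube segments (≈ 100 inner-wall molecules,
≈ 200 outer-wall sites), 40-step recovery trajectories, and 40
disorder realizations for band-averaged quantities, which is ample
because band means average over many grid points and molecules.
Peak-position and width statements use the full 1000-realization
averaging.  The demo pipeline configuration uses an 8 nm segment and
200 realizations; 1000 realizations and a 20 nm segment reproduce the
full-scale setting at proportionally higher cost.

## Known limitations

- The wall lattice is a structurally-motivated placeholder, so absolute
  band positions and shift magnitudes (e.g. the inner-wall shift on
  outer-wall removal, +34 cm⁻¹ in the default detuned double wall) are
  not quantitative predictions; only signs and qualitative orderings
  are asserted.
- A single fixed perpendicular polarization is used rather than an
  average over perpendicular directions; for the (nearly) cylindrical
  configurations studied here the difference is within the disorder
  noise.
- The assembly toy model has no physical timescale; trajectory time is
  measured in steps (or adsorbed-molecule counts), so fitted rates are
  per step.
- Excited-state absorption, exciton transport, vibronic structure and
  periodic-boundary couplings are not modelled.
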