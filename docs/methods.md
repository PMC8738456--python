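# Methods

`virtradiol` is a deterministic simulator of projectional radiography for
teaching: it poses a virtual patient built from closed triangle meshes and
synthesises the radiograph that a given tube/cassette setup would record.
This note describes the models, their assumptions, the numerical choices,
and what the shipped phantoms do and do not demonstrate.

## Image formation

The detector is an ideal planar energy-fluence receptor behind a point
source.  For every pixel `p` the simulator casts one ray from the focal
spot through the pixel centre and evaluates the polychromatic Beer–Lambert
law

    I(p) = mask(p) · Σ_i N(E_i) · E_i · exp(−Σ_m μ_m(E_i) · L_m(p)),

where the outer sum runs over the spectrum bins `(E_i, N_i)`, `μ_m` is the
linear attenuation coefficient of material `m` (cm⁻¹) and `L_m(p)` the path
length of the ray inside that material (cm).  `mask` is the collimator
shadow evaluated on the cassette plane.  Scatter, focal-spot blur, detector
response and MTF are deliberately outside the model: the image is the
primary-beam fluence, nothing else.  Quantum noise — the visible effect of
the mAs setting — can be added afterwards as per-pixel Poisson resampling,
`Poisson(x·s)/s` with a seeded generator; the scale `s`
(`photons_per_unit`) is the mAs surrogate.  For means above 1e12 the
Gaussian limit of the Poisson law is substituted; the error of that
substitution is far below the quantisation of any output format.

### Path lengths (L-buffer)

Interior path lengths through each watertight, outward-oriented mesh are
accumulated per ray as Σ sign(d·n)·t over all ray/triangle intersections —
an exit (d·n > 0) adds its distance, an entry subtracts — so the sum equals
the chord length inside the surface without sorting or pairing hits.
Intersections use vectorised Möller–Trumbore over ray×triangle chunks
(bounded working set), preceded by a per-ray slab test against the mesh
bounding box.  A flat chunked kernel was chosen over a triangle hierarchy:
the phantom meshes stay below a few thousand triangles, where the
vectorised all-pairs kernel is already faster than Python-level tree
traversal, and it is exactly reproducible.

Robustness: hits with |d·n| < 1e-12 (grazing) are discarded; a hit whose
smallest barycentric coordinate lies within 1e-10 of zero sits on an
edge/vertex shared by neighbouring triangles and could be double-counted,
so the ray is flagged and re-cast from an origin offset perpendicular to
the ray (1e-9, 1e-6, then 1e-3 mm).  The same applies when the signed hit
count does not balance.  Residual negative sums are clamped to zero with a
warning.

### Containment ("nesting")

A tissue may declare a containment parent (e.g. trabecular bone inside a
cortical shell): the child's chord is subtracted from the parent's before
per-material aggregation, so the inner mesh displaces the enclosing
material.  Containment is declared in the scene description, not inferred
geometrically — deterministic and cheap.  Hiding the inner tissue restores
the parent's full chord.  Negative effective lengths (an inner mesh poking
through its parent, which linear-blend skinning can produce at strongly
flexed joints) are clamped to zero with a logged count.

## Materials and attenuation

A material is an elemental mass-fraction composition plus a density.
Descriptors accepted: element symbols, compound formulas (converted via
standard atomic weights), percent-mixture strings (`Ti90Al6V4` = 90/6/4 %
by mass), and Hounsfield units.  HU convert through a packaged table of
eight anchor tissues (air −1000 HU through cortical bone 1524 HU and a
dense extrapolation row at 3000 HU), with density and composition
interpolated linearly in HU between anchors; values in [−1050, −1000)
clamp to air.  Compositions are the standard ICRP/ICRU reference tissues.

Mass attenuation coefficients come from packaged per-element text tables
(1–200 keV, 60 log-spaced grid points), combined by the mixture rule
Σ wᵢ(μ/ρ)ᵢ(E) and interpolated log-log linearly in energy, with no
extrapolation outside the tabulated span.  The tables themselves are
generated by a compact analytic cross-section model (the generator script
ships in `scripts/make_attenuation_tables.py`):

* incoherent scattering: the exact Klein–Nishina cross-section per electron
  times Z;
* photoelectric absorption: an empirical power law `100·Z^4.6/E^3.88` barn;
* coherent scattering: `11.61·Z^2.5/E²` barn.

The two empirical terms were calibrated once against standard water
mass-attenuation benchmark values at 20–150 keV (agreement within ≈2%
there; heavier elements and energies below ~5 keV are progressively less
accurate, and K-edges are not modelled).  This accuracy envelope is ample
for a display-referred teaching image; anyone needing dosimetric fidelity
should replace the data files with a standard tabulation — the file format
(two whitespace-delimited columns per element) is the only contract.

## Beam spectra

The default generator is Kramers' bremsstrahlung continuum
`N(E) ∝ (kVp−E)/E` on 1-keV bins up to the tube voltage, hardened by
`exp(−μ_Al(E)·d)` for an aluminium-equivalent filtration thickness
(default 2.5 mm, the regulatory minimum for general radiography), then
rescaled to a total photon budget (default 1e6).  Characteristic anode
lines and the heel effect are not modelled.  Tabulated clinical spectra
can be loaded from two-column text files instead.  Under this model the
mean beam energy rises strictly with both kVp and filtration, and the
transmission of a fixed water slab rises with kVp — the physics behind the
over-/under-exposure behaviour radiography students are taught.

## Acquisition geometry

All geometry is in millimetres.  The cassette frame is centre + unit
normal (toward the source) + in-plane "up"; pixel (0,0) is the top-left
corner seen from the source, rows advance opposite "up", storage is
row-major.  SID and SOD are bookkeeping values with the usual meaning;
SID/SOD is the geometric magnification, and the focus–cassette distance
must equal SID when both are specified.  The collimator is an ideal
rectangle on the cassette plane, centred on the central axis, rotated
about the cassette normal; penumbra is ignored (a point source makes the
aperture shadow and the cassette-plane rectangle equivalent up to scale).

## Patient positioning

Positioning is purely geometric, runs automatically from labelled bone
meshes, and ignores gravity (standing/lying is metadata).  Five stages:

1. **Rigging.**  Each joint of a template skeleton moves to the midpoint
   of the closest point pair between the bone surfaces it connects
   (closest-vertex seed refined by two alternating exact point-to-triangle
   projections).  A joint with a single adjacent bone moves to that mesh's
   extremal point along its principal axis, on the side facing the
   template joint.  Explicit joint positions in the scene description
   override the heuristic.
2. **Volumetrisation.**  A body-centred-cubic lattice at a single spacing
   parameter (default 10 mm at limb scale) fills the skin: two adjacent
   cell centres plus each edge of their shared face form four tetrahedra;
   tetrahedra are kept only when all four vertices lie inside the skin
   (containment by the package's own signed-crossing ray test).  Vertices
   inside a bone mesh take that bone's label; a spacing too coarse to
   label every bone is an error, not a silent degradation.
3. **Weighting.**  For each bone, the discrete Laplace equation with
   uniform (combinatorial) edge weights is solved on the lattice's
   vertex graph — Dirichlet data 1 on the bone's vertices, 0 on all other
   bones' — via one sparse LU factorisation shared across bones.  Rows are
   then normalised to sum to 1.  Uniform weights were preferred over
   cotangent/FEM weights: on the near-uniform BCC lattice they are
   unconditionally stable and the discrete maximum principle keeps every
   weight in [0, 1].
4. **Mapping.**  Every tissue vertex is embedded in its containing
   tetrahedron with barycentric coordinates (KD-tree candidate search over
   tet centroids).  Vertices outside all kept tetrahedra — the skin shell
   the conservative lattice does not cover — take the least-violating
   nearby tetrahedron with its exact affine-extension coordinates, which
   may be negative but still sum to 1.  The linear extrapolation keeps
   rigid and affine cage motions exact for every vertex, at the price of
   possible mild distortion of extrapolated vertices under strongly
   non-affine deformations near a fold; the count is logged.
5. **Skinning.**  Per-bone rigid transforms compose local joint rotations
   down the hierarchy (each joint rotates its subtree about its own rest
   position).  Cage vertices move by linear blending written in
   displacement form, `v' = v + Σ_b w_vb (T_b v − v)`, and tissues follow
   through their barycentric anchors, also as displacements.  The
   displacement form makes the identity pose a bit-exact no-op end to end
   — a posed-at-rest radiograph is byte-identical to an unposed one.
   Linear blending is the simplest scheme consistent with a real-time
   teaching tool; its known candy-wrapper artefacts at large twists are
   accepted and the nesting clamp (above) absorbs the resulting
   bone-through-skin slivers at 90° flexion.

## Phantoms and what the tests show

All test anatomy is generated programmatically: an attenuating slab,
nested spheres and nested cylinders (closed-form chord oracles, exercised
with the same nesting declaration used for trabecular-in-cortical bone),
and a two-bone limb — a 300×⌀80 mm skin cylinder, two ⌀20 mm bone capsules
meeting at a mid-limb elbow with 10 mm end and 20 mm joint clearances, an
ellipsoidal muscle belly offset into the soft tissue, and a matching
three-joint skeleton.  Default materials: water-equivalent skin (HU 0),
cortical bone (HU 1524), soft-tissue muscle (HU 45).

These phantoms verify the geometry, the attenuation arithmetic, the
harmonic-weight theory and the pipeline's determinism exactly; they do not
demonstrate anatomical realism, soft-tissue mechanics, inter-limb
collisions, or image quality on commercial patient models, whose mesh
pathologies (self-intersections, open shells) the loader would reject
rather than repair.  Curved phantom surfaces are polyhedral approximations:
mesh chords agree with the smooth analytic chords only to the facet
sagitta (≈3×10⁻³ cm mean for the default sphere), which is why exactness
checks run against either polyhedrally exact shapes or an independent
interval-pairing ray caster, while the smooth formulas anchor convergence
checks under refinement.

## Determinism and problem sizes

A single config seed drives the only stochastic stage (Poisson noise), so
a run is a pure function of the config bytes, the referenced files and the
seed; manifests record SHA-256 checksums of inputs and outputs.  Default
problem sizes — 256×256 detector pixels, phantom meshes of 0.5–6 k
triangles, cages of ~3–6 k vertices — render a full flexed-limb lesson in
a few seconds on one CPU core, which is the regime a classroom tool should
occupy; resolution, lattice spacing and mesh subdivision are all single
parameters when finer results are wanted.
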