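# Methods

`cotransmap` quantifies the spatial relationship between cytoplasmic
ribosomes and mitochondrial membranes in cryo-electron tomograms. Its
inputs are the two artifacts subtomogram-averaging and membrane-surface
pipelines already produce: a particle table (positions in the tomogram
frame plus an Euler-angle orientation per ribosome) and per-compartment
triangle meshes of the outer and inner mitochondrial membranes (OMM,
IMM). Everything downstream is geometry and nonparametric statistics on
those two objects. All positions and distances are Angstrom; all angles
are degrees; Ripley's-K radii are quoted in nanometres at the module
surface.

## Particle-to-membrane annotation

Orientations are intrinsic ZYZ Euler triplets,
`R = Rz(rot) · Ry(tilt) · Rz(psi)`, mapping particle-frame vectors into
the tomogram frame — the common convention for the `rlnAngleRot/Tilt/Psi`
columns of STAR particle tables. The convention is asserted by a
round-trip test against an independent quaternion implementation. Since
the upstream convention is not always knowable, the conversion is kept
in one function with the convention as an (currently single-valued)
argument rather than scattered through the code.

Functional sites on the ribosome are expressed as fixed particle-frame
offset vectors (`FrameOffset`): the peptide exit tunnel, and the 3' mRNA
entry and 5' mRNA exit channels. A site's tomogram position is
`x + R·v`. These vectors are configuration, not constants: on real data
they come from masking the consensus subtomogram average. The synthetic
defaults are exit tunnel `(0, 0, -120)` (the tunnel opens along -z,
120 A from the particle centre, about the radius of an 80S ribosome) and
mRNA ports `(±105, 0, -40)` (210 A apart across the small subunit,
low on the particle). They are chosen to reproduce realistic scales, not
any particular structure.

Membrane proximity uses a k-d tree over triangle centroids: each
particle gets the id of and distance to its nearest OMM triangle
(`d_center`), and the same query from its shifted exit-tunnel point
(`d_exit`). Centroid distance is the default because it matches the
k-d-tree-over-triangles procedure these analyses conventionally use; an
`exact_surface` mode computes the true point-to-triangle minimum (the
centroid figure overestimates by at most one edge length) with a pruning
bound that keeps it exact. Orientation is summarised by three relative
angles `θ_i = arccos(|v_i · n|)` between the rotated particle axes and
the nearest triangle's unit normal; the modulus folds obtuse angles so
θ ∈ [0°, 90°] and the statistic is invariant to the normal's sign, which
is arbitrary on a reconstructed surface.

## Classification

Two inclusive distance rules partition the annotated particles:

- **import-oriented**: `d_exit ≤ 95 A`. The exit tunnel is close enough
  to the OMM for the nascent chain to engage the import machinery.
- **near-unoriented**: `d_center ≤ 250 A` and not import-oriented — the
  comparison class of membrane-proximal but unengaged ribosomes.

Both cutoffs are configurable (`ClassifierConfig`). The 95 A boundary is
taken inclusive; the boundary case is covered by a dedicated test.
Relative angles are reported but never filtered on — the selection is a
pure distance rule.

## Membrane patches and cristae

A *patch* is the set of mesh triangles whose centroids lie within 150 A
(Euclidean) of a seed triangle's centroid — the footprint of one docked
ribosome. Euclidean rather than geodesic distance is used because
150 A is far below the curvature radius of a mitochondrion, so the two
agree to well under a triangle edge. Patches from nearby particles are
merged by boolean OR into per-triangle labels, so overlapping footprints
are counted once.

Cristae junctions are detected operationally: IMM triangles whose
nearest-OMM-centroid distance falls in the 18-30 nm band (`cj_IMM`),
projected to their nearest OMM triangles (`cj_projected_OMM`), then
expanded by 15 nm — half a cristae-body width — to give
`crista_associated_OMM`. An optional per-triangle exclusion mask stands
in for manual cleanup of band triangles that are not junctions; a
curvature-based detector is deliberately out of scope.

The overlap fraction between two labels is area-weighted:
`Σ area(a ∧ b) / Σ area(a)`, undefined (reported missing, not zero) when
label `a` has no area. Randomized control patches draw seed triangles
uniformly (area-weighted optionally) by rejection until all pairwise
seed separations exceed 150 A; the sampler is seeded and aborts with the
achieved count when the mesh cannot hold the request.

Patchwise inter-membrane distance assigns every OMM triangle its
nearest-IMM-centroid distance and splits the population by patch
membership; the two groups partition the OMM exactly (tested as an area
conservation law). Per-population summaries use the peak of a 100-bin
histogram spanning that population's [min, max], ties broken to the
lower bin. Note this per-population range makes peaks of small and large
samples systematically incomparable at the sub-Angstrom level — the
reason the negative control below compares patch samples to patch
samples.

## Clustering statistics

`K(r)` is the mean number of other particles within distance `r` of a
particle. The CSR reference is estimated by re-placing the same number
of points uniformly by area on the identical OMM mesh (20 independent
replicates by default) and averaging the same statistic, so the reported
quantity is `K_obs(r) / K_CSR(r)`: intensity and geometry factors
cancel, a closed surface has no boundary to edge-correct, and 1 means
"random". The default grid is 1 nm steps over 27-166 nm. Downstream
summaries take the maximum ratio per 10 nm interval, with interval edges
aligned to multiples of the width (so the most diagnostic interval is
[30, 40) nm), and compare interval maxima across tomograms with the
two-sided Mann-Whitney U test (exact for small untied samples,
tie-corrected normal approximation otherwise). Tomograms are the unit of
independence everywhere: group tests always compare per-tomogram
summaries, never pooled triangles or particles.

## Polysome detection

Candidate links between import-oriented particles require (1) centre
distance ≤ 30 nm and (2) the 5' exit port of one particle within
`adj_max` of the 3' entry port of the other. The original adjacency
judgement was visual; here it is an explicit threshold, default 60 A
(three times the 20 A marker-sphere radius used to mark the ports),
configurable and recorded in output metadata. Each particle keeps at
most one incoming and one outgoing link — smallest port gap wins — and
chains are the maximal simple paths of the resulting graph; rare cycles
are broken at their largest port gap. Reported metrics per chain:
`end_to_end`, the straight line between the terminal ports, and
`path_length`, the polyline the putative mRNA traces (inter-member rods
plus the entry-to-exit span across each interior member), which is
always ≥ `end_to_end` by construction.

## The synthetic scene generator

The generator exists so that every stage can be tested against known
ground truth without tomographic data; it is first-class, tested code.

**Membranes.** The OMM is a subdivided icosphere scaled to ellipsoid
semi-axes (default 2000 A, i.e. a small yeast mitochondrion in
cross-section; subdivision depth chosen from the target edge length,
default 50 A). The IMM is the inward normal offset of the OMM by the
boundary gap `ibm_gap` (default 135 A, the centre of the 130-140 A
spacing typical of regions without import activity). Cristae are
Gaussian invaginations: at well-separated random sites the IMM is pushed
inward by `crista_depth` (default 500 A) with lateral scale
`crista_neck_radius` (default 300 A); the falloff annulus sweeps the IMM
through the 18-30 nm detection band, so each crista contributes one
connected band component. Constrictions pull the IMM back toward the OMM
at chosen 3D sites (projected onto the IMM first, so the requested
amplitude is attained exactly at the site) with a Gaussian of scale
`radius`. Infeasible geometry — constriction amplitude ≥ gap, crista
deeper than the organelle — is rejected with a diagnostic. Both meshes
are watertight with outward normals (signed-volume tested) and the IMM
stays strictly inside the OMM.

**Particles.** Particle centres hover 150 A above the OMM along the
local normal (centre-to-membrane distance of a docked 80S). An
import-oriented particle's frame maps z to the outward normal, so the
exit tunnel at -z faces the membrane and `d_exit ≈ 30 A`; non-import
particles are flipped, putting their exit point ~270 A from the
membrane. With zero orientation noise the classes are therefore exactly
recoverable, and the noise parameter degrades this controllably. The
first ⌊f·n⌋ particles are assigned import orientation before a seeded
shuffle, so class counts are exact whenever f·n is an integer. Surface
clustering uses a Thomas process (area-uniform parents, tangent-plane
Gaussian offspring re-projected to the surface, default 10 × 10, spread
15 nm); polysome chains walk approximate geodesics at fixed spacing with
each member's x axis aligned to the walk, which lines up consecutive
exit/entry ports (port gap ≈ spacing − 210 A on a flat membrane, a few
Angstrom wider on the curved one). Ground truth records every particle's
class, cluster parent, chain id and within-chain order.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: tomographic noise and the missing wedge,
template-matching false positives, localisation/orientation error beyond
the isotropic noise parameter, real cristae morphology (sheets, tubes,
stacked lamellae — here they are radial Gaussian invaginations),
membrane undulation at scales below the crista size, partial membranes
at lamella edges, and crowding by other macromolecules. Recovery results
on these scenes demonstrate the correctness of the measurement chain,
not the detectability of effects at realistic noise levels.

## Numerical choices and conventions

- Degenerate (zero-area) mesh faces are dropped at load with a logged
  count rather than raising; screened-Poisson surfaces often carry
  slivers.
- Nearest-triangle queries break exact ties by k-d-tree order; distances
  are exact floating-point comparisons, thresholds inclusive.
- STAR coordinates are taken as 0-based voxel coordinates times the
  voxel size; the voxel size is a mandatory argument in voxel mode and
  never guessed. Tomogram identity reads `rlnMicrographName`, falling
  back to `rlnTomoName`.
- Per-triangle labels travel as PLY face properties (ASCII) or as a
  sidecar CSV keyed by face index next to STL files.
- Histogram-peak ties take the lower bin; interval maxima over an
  interval containing no grid radius are missing, not zero.
- All stochastic components (scene, placement, CSR null, randomized
  patches) consume `numpy.random.Generator` seeds derived from a single
  run seed; reruns are bit-identical.

## Test problem sizes

The suite runs scenes at triangle edge lengths of 100-160 A
(5 120-20 480 faces per mesh) with tens to hundreds of particles, and
the calibration check uses the full default geometry (edge ~50 A, 81 920
faces, 500 particles, 20 null replicates). These sizes were chosen so
each property is measured well inside its noise floor; the recovery
margins (e.g. an in-patch peak 35 A below the out-of-patch peak against
sub-Angstrom peak noise) make the assertions insensitive to the exact
sizes.

## Known limitations

- Centroid-mode distances overestimate true surface distance by up to
  one edge length; on coarse meshes the 95 A rule therefore behaves like
  a slightly stricter rule. Use `exact_surface` mode when mesh edges are
  not small against the cutoffs.
- The crista-junction band rule inherits the operational definition:
  anything in the 18-30 nm band that is not a junction must be removed
  via the exclusion mask.
- The CSR null defaults to the membrane surface (the relevant reference
  for membrane-bound particles); the `shell` null thickens the surface
  by a uniform normal offset for patterns that hover off the membrane,
  but no fully volumetric (bounding-box) null is offered.
- Chain linking is greedy on port gaps; pathological near-tie
  configurations could link differently than a global optimum would.
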