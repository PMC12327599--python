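# Methods

## Scope and data model

`cellshape3d` operates on a 3D labelled image indexed `(z, y, x)` with
0-based integer voxel coordinates, 0 = background, and a physical voxel
spacing `(dz, dy, dx)` in micrometres. Reported coordinates place voxel
centres at integer positions scaled by the voxel size. The package
measures shape and topology only; it neither segments nor repairs
segmentations, and it does not support 2D images. Tissues are assumed
confluent: the neighbour rule below under-reports contacts across large
intercellular gaps.

## Isotropic resampling

Confocal stacks are usually coarser in z than in xy, so all measurements
are made after resampling to cubic voxels. Interpolation is
nearest-neighbour only — any averaging scheme would invent label values at
cell interfaces — and the target spacing is `min(dz, dy, dx)`, i.e. the
volume is upsampled rather than discarding in-plane resolution. The label
set is preserved exactly; per-label voxel counts scale by the volume ratio
up to discretisation (within ±5% for compact cells ≥ 10 voxels across).

## Topology extraction

**Neighbours.** A cell's binary mask is dilated by one voxel and overlaid
on the label image; labels under the dilated shell are the neighbours.
The structuring element is 6-connected (face adjacency). 26-connectivity
would link cells that meet only at a voxel corner or edge, inflating the
adjacency graph; with 6-connectivity the dilate-and-multiply rule is
provably identical to the exhaustive scan over differing-label voxel pairs
sharing a face, which the test suite verifies exactly on randomly seeded
tissues. A single shared voxel face suffices for adjacency; no minimum
contact area is imposed (outlier filtering can prune downstream).

**Faces.** For each adjacent pair the face is the intersection of the two
dilated masks — a two-voxel-thick shell straddling the interface. Faces
are stored as *half-faces*, one record per ordered cell→neighbour pair
with mutual mirror ids; both halves share one pixel set, so mirror
metrics agree by construction. Contacts with background (including the
apical and basal caps of a monolayer) are not faces.

**Edges.** Junctions are enumerated over sorted triplets of mutually
adjacent cells (the triangles of the adjacency graph, which is the
deduplicated form of enumerating 3-combinations over each cell's
neighbourhood); the triple intersection of dilated masks is the junction
curve, kept when nonempty. Restricting to triangles guarantees every edge
is consistent with the graph; degenerate corner configurations in which
two of the three cells meet only diagonally are therefore not reported as
junctions. Four-cell vertices are not extracted. An edge's z-extent may
cover only part of its cells' depth — that is the signature of a scutoid.

**Border cells.** A cell is flagged as a border cell when its in-plane
(lateral) one-voxel shell leaves the array or is ≥ 5% background. The
criterion is deliberately lateral: in a monolayer every cell touches the
top and bottom of the stack, which says nothing about whether its faces
are completely captured. Faces and edges of border cells are only
partially extracted.

**Per-plane neighbours.** For each occupied z-plane the cell's 2D slice is
dilated with the 4-connected element and overlaid on the label plane.
4-connectivity in 2D is the in-plane restriction of 6-connectivity in 3D,
so for columnar tissues the union of per-plane neighbour sets equals the
3D neighbour set. Cells stacked purely along z are 3D neighbours that
appear in no plane set; such contacts do not occur in the monolayer
fixtures used here.

## Scutoid detection

A cell is flagged as a scutoid when its per-plane neighbour set changes
between any two occupied planes; the reported exchange planes are the z
indices whose set differs from the occupied plane below. Planes where the
cell has fewer than 4 voxels are ignored, because tapering cell tips
produce spurious set changes. The detector reports *any* apico-basal
neighbourhood change: a neighbour that simply ends mid-depth is flagged
too. This sensitivity is documented and tested; distinguishing true
T1-like exchanges from neighbour termination would require information the
label image does not carry.

## Cell metrics

* **Volume** `V` = voxel count × voxel volume.
* **Surface area** `A` = count of exposed voxel faces × (voxel edge)².
  Exposed-face counting is the standard voxel surface estimator and
  overestimates smooth surfaces — by a factor ≈ 1.5 for a ball, which the
  tests reproduce (1.5004 at radius 20). Consequently the voxel
  sphericity of a digitised ball is ≈ 0.67 rather than 1.
* **Centreline** — the polyline of per-plane voxel centroids. If the major
  axis (first principal axis of the voxel-coordinate cloud) is tilted more
  than 30° to z, the cloud is rotated so the axis aligns with z, centroids
  are taken in unit-width slabs along the rotated axis, and the polyline
  is rotated back. Rotating the point cloud rather than the raster avoids
  resampling artefacts. Sparse end slabs (< half the median slab
  occupancy) are trimmed, since slabs perpendicular to the axis clip the
  cell's caps and drag the end centroids inward; at 45° discretisation a
  residual ~1-voxel corner bias at the caps remains. The 30° threshold
  means squat cells (major axis in-plane) are reoriented as well; for such
  cells the "centreline" runs along the in-plane axis, which is why twist
  tracing (below) uses the plain per-z centroid line instead.
* **Straightness** `t_s = 1 − l_short / l_real`, where `l_short` is the
  first-to-last-point distance and `l_real` the polyline arc length; 0 for
  a perfect column. Scale- and rotation-invariant.
* **Sphericity** `Ψ = π^(1/3) (6V)^(2/3) / A` (Wadell's definition): 1 for
  the analytic sphere, `(π/6)^(1/3) ≈ 0.80600` for the cube, decreasing
  with elongation.
* **Orientation** — plane angles of the major axis projected into xy, xz
  and zy, measured from the first named axis of each plane (x, x, z),
  counter-clockwise positive, in (−90°, 90°]; tilt to z in [0°, 90°].
  A degenerate (isotropic) covariance reports zero angles with a flag.

## Per-plane metrics

2D area and perimeter are pixel counts (perimeter counts exposed pixel
edges, consistent with the 3D estimator and likewise an overestimate of
smooth outlines). Orientation, anisotropy and major axis come from the
second-moment ellipse with the standard 1/12 unit-pixel term, so an
axis-aligned a×b rectangle reports anisotropy exactly a/b. Anisotropy is
the major/minor axis ratio (≥ 1; 1 by convention for a single pixel). The
2D-vs-3D neighbour comparison uses the highest occupied plane as the
apical proxy.

## Face and edge geometry

The face pixel cloud is centred and decomposed by SVD: the two leading
right singular vectors span the best-fitting plane, the third is the
normal, and **flatness** `f` is the population variance along the normal
(µm²; 0 exactly for coplanar pixels, invariant under rigid motion).
Projected **area/perimeter** rasterise the in-plane coordinates into bins
of one voxel edge, so a flat axis-aligned wall reproduces its raw pixel
counts; folded or strongly bent faces are underestimated by the
projection, and the fit itself is unreliable for such faces. Per-plane
face **length** orders each plane's pixels by their principal 2D
direction, bins them at unit width, and measures the polyline through bin
means (a straight wall of width w reports w − 1 unit steps); the angle is
the principal direction's xy orientation in (−90°, 90°].

**Edge geometry** reduces each junction to its per-plane mean positions;
tortuosity applies the `1 − straight/real` form to that polyline.
Single-plane edges are degenerate (lengths 0, tortuosity absent).

**Twist.** For every incident edge and plane, the xy angle of the vector
from the cell's per-plane centroid to the edge position is taken (signed,
right-handed about +z). Each edge's angle profile is unwrapped along z by
accumulating smallest signed differences, referenced to its first plane;
per-plane rotation is the mean over edges (≥ 2 edges spanning ≥ 3 planes
required), total twist is the rotation at the last plane, and the twist
rate divides by the centreline length. For off-axis cells the centreline
is a helix slightly longer than the cell height, so the per-µm rate is a
slight underestimate of a per-plane imposed rate; recovery is therefore
validated in °/plane.

## Synthetic tissues

The generators emulate the construction used for validating this class of
tool: a 2D Voronoi pavement (pixels labelled by nearest seed) replicated
across z gives a columnar tissue with exactly known adjacency, areas and
centroids. Seeds are drawn uniformly with a minimum separation of 0.3 ×
the expected spacing `sqrt(area/n)` to avoid sliver cells; labels are
1..n in seed order; everything is deterministic given the rng seed.

* **Scutoid** — one adjacent seed pair is moved apart along its connecting
  line (trying increasing displacements, then other pairs, with bounded
  retries) until the pavement adjacency changes: their shared wall
  collapses and the two flanking cells gain one, a T1-like exchange.
  Planes below the exchange plane use the original pavement, planes above
  the perturbed one. Ground truth is the set of cells whose pavement
  adjacency differs. Every cell's two regions must overlap in xy so cells
  remain 6-connected columns.
* **Tilted** — the pavement is shifted by `round(tan(tilt)·z)` pixels per
  plane along x, with the domain padded for the shear. Threshold behaviour
  is validated on slender columns (height ≈ 80, width ≈ 12 voxels):
  principal-axis tilt of a sheared column is biased upward by the
  cross-section width, and slender proportions keep that bias ≈ 0.5°, so
  the 29°/31° fixtures fall cleanly on either side of the 30° threshold.
* **Twisted** — a disk-masked pavement rotated by (rate × z)° per plane
  about the patch centre, nearest-neighbour resampled. Because each plane
  rotates rigidly, every interior junction rotates about every interior
  cell's centroid at exactly the imposed rate, regardless of the cell's
  distance from the patch centre.
* **Resize/crop variants** — nearest-neighbour resize to a target shape
  (upsampling preserves the adjacency graph exactly) and border-cropping
  (removing all cells touching the xy boundary) reproduce the image-size
  and cell-number comparisons at constant average cell size.

What the fixtures do **not** emulate: curved monolayers, real
segmentation noise (rough interfaces, mis-segmentation), intercellular
gaps, and anisotropic acquisition blur. Passing tests therefore establish
the correctness of the decomposition and metrics on clean confluent
geometry, not robustness to segmentation error.

## Numerical choices and degenerate inputs

Fixed tolerances: isotropy check at 1e-9 relative; plane-fit collinearity
at `s₁ < 1e-9·s₀`; flatness of exact lattice planes is 0 to < 1e-12 µm².
Problem sizes in tests and the acceptance script (50 tissues of
150×200×200 voxels for graph equivalence; 20 exchange tissues of
16×120×120; 20-plane twisted and 80-plane tilted fixtures; one
500×500×150, ~70-cell benchmark tissue) were chosen to exercise the
method at realistic cell counts while keeping a full run to a few
minutes on one CPU. Degenerate inputs are explicit errors or flagged
absences, never silent numbers: single-plane cells (no centreline, no
scutoid call), < 3 or collinear face pixels (no plane fit), single-plane
edges (no tortuosity), < 2 usable edges (no twist), isotropic covariance
(zero angles + flag). Filtering of metric tables is post hoc, idempotent
and order-independent; it removes rows, never re-extracts topology.

## Known limitations

* Voxel surface area and perimeter systematically overestimate smooth
  boundaries; sphericity values are comparable within-method only.
* Scutoid detection cannot distinguish neighbour exchange from a
  neighbour ending mid-depth.
* Faces that bend strongly violate the single-plane projection; their
  area/perimeter are underestimated and flatness is the only warning.
* Junctions where two of three cells meet only corner-to-corner are not
  extracted (6-connectivity choice).
* Tissues with large intercellular spaces break the close-contact
  assumption of the dilate-and-multiply rule.
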