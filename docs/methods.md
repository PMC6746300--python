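# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `chearray`, in the order of the pipeline.

## Idealized array lattice

The baseplate of the chemosensory array is modelled as two interleaved
lattices in the XY plane (receptor axis +Z, ring centers at z = 0):

- **Ring centers** form a triangular lattice with repeat
  `lattice_constant` L (default 120 Å, the 12 nm spacing of native and
  reconstituted arrays).  Internally the lattice is generated from
  primitive vectors t₁ = L(1,0), t₂ = L(½, √3/2); a face at integer
  coordinates (i, j) has color (i − j) mod 3, the standard three-coloring
  in which the six neighbors of any face carry the two other colors.
  Color 0 is the CheW-only ring sublattice (the face containing the origin,
  fixing the otherwise arbitrary phase deterministically), colors 1 and 2
  the two kinase-filled sublattices.
- **TODs** sit at the honeycomb vertices — the centers of the up/down
  triangles of the ring lattice — giving a nearest-neighbor TOD distance of
  L/√3 ≈ 69.3 Å and six TODs per unit cell.

The unit cell is the √3×√3 R30° supercell of the ring lattice:
a = b = L√3 (≈ 208 Å at the default L), γ = 120°, c = `box_height`
(default 334 Å).  Comparisons against the printed 208 Å use nearest-Å
rounding; the full-precision value is 207.846 Å.

A CheA dimer is placed at the midpoint of every adjacency between a
color-1 and a color-2 face, its two P5 domains assigned to the two flanking
kinase rings; each kinase ring then alternates three P5 (traced to three
distinct dimers) with three CheW, and each CheW-only ring takes six CheW.
Each TOD contributes one receptor dimer to each of its three incident rings
(a honeycomb vertex touches one face of each color).  Interface labels
around kinase rings alternate 1, 2 by slot parity.

Core-signaling units (2 TOD + 1 CheA dimer + 4 CheW) are assigned
deterministically: a dimer owns the two TODs at the endpoints of its
shared ring-lattice edge (each TOD is the endpoint of exactly one such
edge, so core units partition the lattice), the CheW monomer one slot
counterclockwise of each of its P5 domains, and each owned TOD's member in
its CheW-only ring.  Motifs are unions of core units: trimer = the three
units around one kinase ring, hexamer = the six units around one CheW-only
ring (requires a ≥ 2×2 supercell so the six dimers are distinct on the
torus), unit cell = the three units of one cell.

Placements are generated on a torus (periodic wrap) so per-cell counts are
exact at every supercell size; the real monolayer edge behavior is not
modelled.  TOD orientations are C3 about Z with the x axis toward the first
incident ring; dimer x axes point along their ring-ring adjacency.  The
z offsets between receptor tips, ring plane and kinase layer are exposed as
parameters (`tod_z_offset`, default 0) rather than given structural
defaults, since the builder is geometric, not atomic.

## Map simulation and FSC

`simulate_map` renders coordinates as normalized isotropic Gaussians with
σ = resolution/(π√2), the Fourier-criterion convention under which the
kernel amplitude falls to e⁻¹ at spatial frequency 1/resolution; kernels
are truncated at 5.5 σ and the grid integral of the map equals the total
weight.  All tests of map operations use convention-free relative
properties, so another σ convention would only rescale nominal resolutions.

FSC uses the real part of the normalized complex cross-correlation per
shell; shells are half-open [k, k+Δk) of one Fourier-voxel width
(Δk = 1/(N·voxel) with N the largest dimension), up to Nyquist.  Conical
FSC restricts each shell to the double cone of half-angle 42° (default)
about an axis; the default axis set is the 3 principal axes plus the 10
antipodally distinct bisectors (six (1,±1,0)/√2-type, four (1,±1,±1)/√3-
type).  Cone shells with fewer than 10 voxels are flagged (NaN) and skipped
by the resolution estimator, which otherwise reports the reciprocal of the
first linearly interpolated crossing of the threshold (default 0.143) and
falls back to Nyquist, flagged, when the curve never crosses.

The anisotropic filter attenuates every Fourier voxel with a raised-cosine
low-pass at the cutoff of the cone(s) containing it — overlapping cones
average their cutoffs, voxels outside all cones use the mean cutoff
("mean" policy; "strict" raises instead — the adjustment for overlapping
cone regions is otherwise underdetermined).  The soft edge spans two
Fourier voxels.  Filtering is exactly idempotent only where the pass-band
already contains all signal; re-filtering changes a map by <1% (voxelwise,
relative to the map maximum) when the map is bandlimited below the cutoffs,
which is the realistic case of re-filtering an already filtered average.
The filter defaults to the three principal cones, with the 13-axis set
available.

MRC2014 I/O (mode 2, X fastest, voxel size from the cell, origin in the
ORIGIN header words) goes through gemmi.

## Rigid-body docking

The protocol follows the exhaustive-start design: `n_starts` (default
10,000) uniform random orientations with translations uniform in the closed
ball of `max_shift` (default 20 Å) around the template center of mass
(uniform-in-ball chosen over per-axis uniform, which the protocol leaves
open).  The sampler's mean rotation angle, π/2 + 2/π rad ≈ 126.48°, is the
closed form for the uniform rotation distribution and serves as its
statistical check.

**Score.**  The score of a pose is the global normalized (Pearson)
cross-correlation between the target map and the Gaussian-kernel simulation
of the posed template on the same grid.  It is evaluated through an exact
factorization: the template's self-overlap ∑ᵢⱼ wᵢwⱼ N_{σ√2}(dᵢⱼ) is
pose-invariant, the template mass is constant, and the template–map overlap
equals the Gaussian-smoothed target (computed once in Fourier space with
the exact transfer function) sampled at the posed bead positions with a
quintic spline.  One evaluation therefore costs O(n_beads) and reproduces
the direct grid correlation to ~10⁻⁴; at the exact generating pose the
score exceeds 0.999.  A mask restricted to the template support would
differ only when the target contains additional structure outside the
template; the synthetic single-domain targets this package scores do not,
and the global form is what makes the 10⁴-start protocol tractable on one
CPU.

**Refinement.**  Each start ascends the score by cyclic coordinate ascent
over the six rigid degrees of freedom (world-axis rotations and axis
shifts, accepted moves repeated while improving, so the score trace is
monotone).  A continuation stage precedes the true landscape: the same
target scored with a 4× wider kernel is far smoother (approximately the
mass-quadrupole alignment problem), and coarse steps from (32°, 8 Å) walk
most starts into its dominant basin; because second moments cannot
distinguish 180° flips about the principal axes, a discrete flip test over
those three rotations follows before the fine stage halves steps down to
(0.25°, 0.25 Å).  Convergence flags report whether the finest level
finished within the sweep budget.  On the toy P4 target at 12 Å this
two-stage scheme sends ~60–70% of uniformly random starts into the planted
pose's class; single-stage ascent at the target resolution reaches only a
few percent.

**Clustering.**  Fits are visited in descending score order and join the
first class whose representative is within both 3° (geodesic rotation
distance 2·arccos(|q₁·q₂|), double-cover safe) and 3 Å; otherwise they
found a class.  Ranking is by representative score; occupancies partition
the fit set.  Score rank does not track class size, so recovered classes
are matched to planted poses with `match_class_to_pose` when comparing
against ground truth.  Linker feasibility bounds the anchor–terminus
distance by n_residues × 3.8 Å (Cα–Cα contour proxy).

## Dipping-switch analysis

Frames are aligned to a reference by least-squares superposition (batched
Kabsch with determinant correction) on an alignment selection — by default
the P5 domains, residues 543–671, inclusive on both ends, author numbering.
PCA is computed on the alpha carbons of the P4 domains (residues 352–542;
the selection also filters on the domain tag because receptor anchor beads
reuse receptor residue numbers in that range), unweighted, via SVD of the
centered frame matrix.  The sign of each retained component is oriented so
its projection distribution has non-negative skewness, which puts a
minority dipped state on the positive side; the sign is otherwise arbitrary
in PCA.

Dip events are maximal runs of a Schmitt trigger on the PC1 projection:
enter dipped above threshold + h, leave below threshold − h.  The default
threshold is the midpoint of a two-component Gaussian mixture fitted to the
series with h = 0.5 of the mean component σ; when the two components are
separated by less than 3 pooled σ the series is treated as unimodal and a
one-sided guard at mean + 5 σ is used instead, so pure-noise series yield
no events.  Events longer than `min_duration` (default 10 ns) are flagged
extended.  `annotate_events` marks an event as carrying a stabilizing
contact when the pair is bound for ≥ 50% of the event's frames.

Pairwise RMSD matrices are computed over a selection of frames pre-aligned
to a single common reference (not per-pair re-superposed), which makes
rmsd = ‖Xᵢ − Xⱼ‖/√m an exact Euclidean metric; UPGMC is then
`scipy.cluster.hierarchy.linkage(method="centroid")` on the condensed
matrix, exact for Euclidean input.  Cluster ids are relabelled by
descending population; dendrograms export as Newick.  The cut is supplied
as `n_clusters` (the cut rule behind "major clusters" is not stated;
a largest-gap option is not the default).  The 1,500-frames-per-unit
subsampling convention is implemented as a uniform stride.

Salt-bridge occupancy is the fraction of frames in which the minimum
distance between the two residues' atom sets (single proxy beads in the toy
model) is ≤ 4.5 Å, the standard salt-bridge criterion; the
T. maritima ↔ E. coli residue correspondences ship as a static table
(`TM_TO_ECOLI`), not computed by alignment.

## Synthetic generators

The toy dimer has one bead per residue on two chains with the real CheA
domain boundaries (P3 290–351, P4 352–542, P5 543–671).  Chain A's P4 is a
three-lobed chiral cluster (120 + 47 + 24 beads on deterministic Fibonacci
shells) so that its docking orientation is identifiable at ~10 Å simulated
resolution and no improper rotation maps it onto itself (mirror RMSD
> 1 Å).  The dip is a rigid rotation of chain A's P4 about the P3–P4 hinge
(default 25°, a fixture scale chosen so the planted PC1 separation is far
above the σ = 0.5 Å thermal noise — not a claim about the real hinge
angle) plus a 5 Å shift of the lower P3 bundle (residues ≥ 320).
Contact-proxy beads are positioned so the geometry enforces the state
linkage: receptor bead K390 (R379) sits 2.5 Å from the undipped D333
(D345) position and is left behind by the P3 shift; the dipped positions of
E397 and E390 land 2.5 Å from the static R297 bead and the receptor-tip
R379 bead respectively, and are > 4.5 Å away undipped because their
long lever arms move them ~10 Å.  The R297A-like mutant displaces the 297
bead so the dipped-state bridge cannot form and multiplies the undip rate
by 5 (the destabilized dipped state).

Switching is a discrete-time two-state Markov chain at frame resolution
(transition probability 1 − e^(−k·Δt); Δt default 0.02 ns, echoing the
per-frame granularity of ~23,000-frame production trajectories).  Default
rates k_dip = 0.02/ns, k_undip = 0.05/ns give a mean dipped dwell of 20 ns
— so both short and extended (>10 ns) events occur in a 200 ns run — and a
stationary dipped fraction of 2/7.  Gaussian noise (σ = 0.5 Å i.i.d. per
bead) and an optional rigid random-walk drift are added on top; ground
truth records states, events, contact intervals and the stationary
distribution.  The long-run occupancy check inflates the binomial standard
error by the Markov autocorrelation factor √((1+ρ)/(1−ρ)),
ρ = e^(−(k_dip+k_undip)Δt); the naive binomial SE would be badly
anti-conservative for an autocorrelated chain.

Half-map pairs share a noise-free simulated signal plus independent noise:
`shell` mode shapes each half's Fourier noise power to (signal shell
power)/snr, so the expected FSC is snr/(snr+1) in every signal-bearing
shell — the calibration fixture; `white` mode adds flat noise of variance
var(signal)/snr, giving realistically falling FSC curves for resolution
fixtures.  Directional degradation multiplies the noiseless signal of both
halves by a factor < 1 inside a 42° double cone.  The isotropy fixture for
conical FSC is a single Gaussian blob on a cubic grid: its spectrum is
smooth, monotone and exactly isotropic, so the 13-axis resolution spread
measures only estimator noise (multi-bead clouds add speckle and shape
anisotropy that the cones genuinely detect).

Fit ensembles draw component labels from the planted weights and jitter
each pose by a half-normal angle about a random axis and a half-normal
shift along a random direction, so the jitter sigmas bound the pose
displacement directly; scores decrease linearly with distance from the
planted pose.

## Problem sizes

The test suite and acceptance script run, on one CPU in a few minutes:
lattices up to 3×3 supercells; 48³–64³ maps with 50-replicate FSC
calibration; docking with 1,000 starts on a 64³ target at 12 Å (the
protocol default of 10,000 starts scales linearly and is exercised through
the CLI); switching trajectories of 10,000 frames (200 ns) with ~770
beads; 2,000-frame clustering; and 24 pooled trajectories for the
wild-type/mutant dwell-time comparison (one-sided Mann–Whitney).

## Limitations

- The toy dimer is a labelled topology, not a physical model: no force
  field, no solvent, no receptor array around the dimer; passing tests
  demonstrate that the *pipeline* recovers planted structure, not that the
  real array behaves like the generator.
- The real maps' CTF-envelope sharpening is not implemented; map
  comparisons start from simulated or deposited maps.
- Docking scores are global correlations; targets with substantial density
  outside the docked domain would need the (slower) masked variant of the
  score, which this package does not implement.
- The dip threshold's mixture fit assumes at most two dominant projection
  modes; trajectories with several distinct minor states may need an
  explicit threshold.
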