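# Methods

`scaffoldchar` quantifies the microstructure of highly porous, freeze-dried
(lyophilized) collagen scaffolds from 3D image volumes, and the distribution
of cell nuclei in fluorescence z-stacks of seeded scaffolds. All physical
quantities are in micrometres; volumes are (z, y, x) with isotropic voxels,
axis 0 the scaffold thickness and depth 0 at the top face.

## Segmentation

Grayscale micro-CT volumes are binarized at the Otsu threshold — the value
maximizing between-class variance of the intensity histogram (256 uniform
bins over the observed range, matching 8-bit CT exports). The threshold is
computed volumetrically on the full 3D histogram by default; a per-slice
mode exists behind a flag but is off, since slice-wise thresholds drift with
local artefacts. A constant image has no two-class structure and is
rejected ("degenerate histogram").

Despeckling removes spurious components. The default `keep_largest` policy
retains the largest 26-connected pore component, then the largest
6-connected solid component, reassigning orphans to the other phase; the
26/6 pair is the standard dual connectivity that avoids topological
paradoxes between a phase and its complement. A `min_size` policy removes
components below a voxel-count threshold from both phases instead (pore
first, then solid). Note the two passes are not order-free: filling small
solid components grows the pore phase, so the output is not a subset of the
input pore mask. Both policies are idempotent.

## Pore size: maximal-inscribed-sphere local thickness

The pore size at a voxel is the diameter of the largest sphere fully
contained in the pore phase that contains that voxel (Hildebrand &
Rüegsegger's local thickness — the definition used by CT-analysis software
for "3D pore size"). Implementation: the Euclidean distance transform (EDT)
gives each candidate centre's inscribed radius; candidate centres are swept
in descending half-voxel radius bands, and coverage is tested against each
centre's *exact* EDT radius (`distance_transform_edt(..., return_indices)`),
so the only approximation is which centre covers a voxel, not how far it
reaches. Every pore voxel is at least covered by its own inscribed sphere
(2·EDT lower bound). Agreement with an exhaustive inscribed-sphere search is
within one voxel on random scaffolds (tested).

The array border is treated as open — inscribed spheres may protrude outside
the grid — which avoids the systematic underestimate a closed border would
cause at the faces. Edge bias is instead handled in the summary statistics:
a guard band of one pore diameter (99th percentile of the thickness map,
capped at a quarter of each axis extent) is excluded from the mean/SD and
histogram. Statistics are voxel-weighted, not per-pore-object: pores in an
interconnected foam are not separable objects, and voxel weighting is the
convention of the CT-analysis tools this mirrors. Wall thickness, if
wanted, is the same computation on the inverted mask.

## Percolation diameter

The percolation diameter d_c is the diameter of the largest spherical probe
able to traverse an infinitely large sample. For a finite slab the package
measures, for each probe diameter d, the accessible region ("shrink wrap"):
erode the pore phase by a digital Euclidean ball of radius d/2 (EDT
thresholding, exactly dual to erosion by the ball {x : |x| ≤ r}), keep the
eroded components 26-connected to the inlet face, dilate back by the same
ball, and intersect with the pore phase. The penetration length L is the
region's reach from the inlet face along the percolation axis,
(1 + deepest slice index)·voxel; the accessible-volume alternative is not
implemented because reach is the natural meaning of "length of the volume
accessible" for a slab. The probe enters from a single inlet face (`z-`
by default), which stays open — the probe may protrude out of it — while
every other face is sealed with a solid layer during erosion. Sealing
matters: with fully open borders a probe can bypass constrictions by
slipping along pores clipped by the array faces, where the constraining
walls lie outside the grid (on the sphere-lattice fixture this inflated
d_c by ~40%).

**Digital monotonicity.** In the continuum, a smaller sphere reaches
everywhere a larger one does, so regions nest and L(d) is non-increasing.
Voxelized Euclidean balls of different radii are not morphological
multiples of each other, and the raw erode/flood/dilate region can miss a
few diagonal boundary voxels that the next-larger probe covers (the
erosion+flood position sets do nest rigorously; only the dilate-back step
breaks it). The package therefore quantizes probe diameters up to whole
voxels and defines the accessible region at d as the union of raw regions
over all grid diameters ≥ d — the continuum closure. Nesting and L
monotonicity are then exact for every probe pair, at the cost of at most a
one-voxel coarsening of the probe diameter. `percolation_curve` computes
the whole family in one descending sweep, so each raw region is evaluated
once; the default grid runs from 2 voxels to the maximal inscribed-sphere
diameter in steps of 1 voxel, with one bisection refinement at the
saturation knee and at the accessibility limit.

d_c is estimated from the scaling law of percolation theory,

    L = L0 · (d − d_c)^(−ν),   ν = 0.88 (universal 3D exponent, fixed),

by ordinary least squares of d against x = L^(−1/ν): d_c is the intercept
at x = 0 and the slope equals L0^(1/ν). Saturated points (the probe
traverses the whole slab) and inaccessible points (L = 0) lie outside the
diverging-but-finite regime the law describes and are excluded; fewer than
3 qualifying points, a flat L plateau, or a non-positive slope raise an
error rather than returning a silent extrapolation. For step-like curves —
an open channel, a window-limited sphere lattice — there is no diverging
regime at all (L drops from saturation straight to a plateau), so
`estimate_percolation_diameter` falls back to the breakthrough diameter:
the largest d whose region still spans the slab, which is exact for such
geometries. The fit is preferred whenever the unsaturated regime has ≥ 3
points and shows actual divergence (largest unsaturated L at least twice
the smallest).

## Cell quantification

Nuclei are detected as local maxima of a scale-normalized
Laplacian-of-Gaussian response at σ = expected radius / √3 (the scale whose
LoG response peaks for a solid 3D blob of that radius), with non-maximum
suppression at one nucleus diameter and parabolic sub-voxel refinement per
axis. The default response floor is five robust noise SDs (median absolute
deviation), which keeps blank and low-SNR stacks clean; an absolute
intensity floor on the Gaussian-smoothed image can be supplied instead.
Defaults (6 µm radius) were chosen against synthetic ground truth, since
tracking-tool parameters for such data are rarely reported.

Surface density is areal — nuclei within the top 100 µm window divided by
the field area, in cells/mm² (the standard readout when each scaffold
surface is imaged as a fixed-depth stack); the depth distribution through a
cross-section is volumetric, cells/mm³ per depth bin. Depth is measured
from the first slice; `from_bottom` flips it. Validation matches detections
to ground truth one-to-one, greedily by distance, within one nucleus
radius.

## Synthetic data

The generators define the study conditions for every test; all are pure
functions of their arguments including the seed (per-call random streams,
never global).

**Lyophilized proxy.** Ice-crystal domains are modelled as the cells of a
nearest-site tessellation (Voronoi-like) of uniformly sampled nucleation
sites — geometry only, no heat-transfer or phase-field physics. Solid
walls of fixed thickness (1.5 voxels by default) form where the nearest
two sites are nearly equidistant (|d2 − d1| ≤ wall); walls are opened into
interconnection windows away from the triple junctions (wall kept only
where d3 − d2 ≤ 0.15 × spacing), which mimics the incomplete walls of a
freeze-dried foam and keeps the pore phase connected. The mask is reduced
to one pore and one solid component so it is a fixed point of despeckling.
Porosity lands in 0.85–0.97 for pore sizes from roughly 7 voxels up (at
the 2.97 µm scan scale: the study's 66/101/143 µm scaffolds); smaller
cells leave proportionally more wall. The band itself is a generator
convention — the source measurements do not report porosity.

The nucleation density is set from the target mean pore size by a
calibration measured once on a pilot sweep (11 spacings, two seeds each,
96³–128³ grids) and frozen: measured mean thickness per site spacing
drifts from ~0.74 (small cells) to ~1.1 (very open foams), so the map is a
piecewise-linear interpolation of the pilot table rather than a single
proportionality constant. Within the calibrated range and with at least 3
tessellation cells per axis (enforced as a precondition), the realized
mean pore size lands within 20% of target; 128³ volumes at ~3 µm voxels —
the scale used throughout the tests — sit comfortably inside that range.

**Analytic fixtures.** A straight circular channel has mean pore size and
percolation diameter both equal to its diameter, exactly. A simple cubic
lattice of spherical pores (diameter D) overlapping in circular windows
(diameter w < D; lattice spacing a = 2·√(R² − (w/2)²)) has mean pore size D
and percolation diameter w, exactly — the fixture that demonstrates pore
size and interconnectivity are measured independently. Sphere centres are
anchored at the origin so the boundary faces cut through pore bodies and
probes can enter.

**Renderings and nuclei stacks.** Grayscale rendering draws each voxel
from a Gaussian centred on its phase intensity (pores darker by default,
as in CT of collagen); blob-SNR for nuclei stacks is peak amplitude /
noise SD. Nuclei are isotropic Gaussian blobs (σ = one nucleus radius)
placed uniformly in the plane (with a one-radius margin so blobs are not
clipped) and by a chosen depth profile: uniform, surface-weighted
(exponential with length scale depth/3, truncated), or a user-supplied
density. Dart throwing enforces a minimum separation when requested.

What the generators deliberately do not emulate: reconstruction artefacts,
beam hardening, anisotropic ice growth, partial-volume gray levels, wall
texture, or optically sectioned PSF anisotropy in z. Passing tests
therefore demonstrate correctness of the measurement definitions on known
geometry, not robustness to every instrument artefact of real scans.

## Numerical conventions

- Squared Euclidean distances on the voxel grid are integers; all
  erosion/dilation comparisons are done on squared distances with a 1e-6
  slack that absorbs float round-off but can never move a half voxel.
- Local thickness radius bands: 0.5 voxel (diameter resolution 1 voxel).
- Probe diameters quantized up to whole voxels (see above).
- Histogram bin edges snap to multiples of the bin width; voxel-weighted
  SD is the population SD.
- Degenerate inputs error loudly: constant images, empty phases, flat
  percolation curves, windows ≥ pore diameters, probes below one voxel.

## Problem sizes

The test suite and the acceptance script run channel fixtures and the
sphere lattice at 128³, scaffold proxies at 128³ (66 and 101 µm targets)
and 144³ (143 µm, which needs ≥ 3 cells per axis), the thickness/
accessibility oracle comparisons at 64³ with 100 sampled voxels and 5
probe diameters, and nuclei recovery on 20 stacks of a 200 × 200 × 60 µm
field plus one 1.417 × 1.417 mm field at 4 µm voxels. These sizes hold the
statistical behaviour of interest while keeping a full run in minutes on
one CPU.

## Known limitations

- The percolation estimate depends on slab thickness through the
  unsaturated regime; very thin slabs leave too few qualifying points and
  error out rather than extrapolate.
- Probe-diameter quantization means d_c inherits a one-voxel granularity;
  report voxel size with results.
- The lyophilized proxy's calibration is empirical and volume-scale
  dependent at the largest pore sizes (fewest cells per volume); outside
  ~3.5 cells per axis the realized mean drifts upward.
- Nuclei detection assumes roughly isotropic, roughly Gaussian nuclei of a
  known scale; clumped nuclei closer than one diameter are merged by
  design (non-maximum suppression).
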