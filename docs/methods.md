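# Methods

This note documents the models, conventions, parameter choices and known
limitations of the pipeline. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and view conventions

Volumes are numpy arrays indexed `[z, y, x]`; physical coordinates are
(x, y, z) in nm with 0-based, voxel-centered indexing and right-handed
axes. z is the slab normal. A conical view is parameterised by Euler
angles (α, β, γ): azimuth α about specimen z applied first, tilt β about
the laboratory x axis, then an in-plane detector rotation γ. A specimen
point **r** appears at the (x, y) components of Rz(γ)Rx(β)Rz(α)**r**, and
the beam integrates along laboratory z. Image shifts are applied after an
in-plane magnification s (shrinkage < 1): u = s·(R**r**)ₓ + shift + image
center. This one convention is shared by simulation, alignment solving,
re-projection and back projection, so round-trip tests are meaningful.

## Phantom model

The generator emulates the statistical structure of a thin (~50 nm)
section through a rod-spherule / horizontal-cell contact:

- Membranes are triple-layered: two Gaussian dense layers (σ = max(s/4,
  0.55·voxel)) flanking a lucent core; the layer-center spacing s (3 or
  6 nm) is the resolution proxy measured later. A parallel horizontal-cell
  membrane sits across a 16 nm cleft.
- Vesicles are bilayer shells with leaflet radii d/2 and d/2 − s
  (d = 40 nm default), so a line profile through a vesicle center shows
  two density humps ≈ d − s apart. Fusion states are geometric: docked
  vesicles touch the membrane and share a single merged leaflet across a
  contact disc (lumen sealed); omega figures sit at d/2 − s/2 from the
  midplane with an open pore (0.3 d radius) carved through both the shell
  cap and the membrane into the cleft; coated vesicles carry an extra
  dense shell 8 nm outside the membrane. Tethered is positional (within
  60 nm of the ribbon).
- The crescent ribbon is a 30 nm plate anchored ~55 nm off the membrane
  by an arciform-density sphere; both are rendered as smooth-edged solids
  (their internal substructure is out of scope).
- Placement is dart throwing with rejection and loud failure. Cytoplasmic
  vesicles enforce pairwise minimum spacings drawn uniformly from
  110–120 nm; membrane-bound pools (docked + omega, placed jointly and
  then assigned states) use a 46 nm minimum, because the reported docked
  areal density (~150/µm²) is unreachable under a 110 nm minimum
  (hexagonal packing at 110 nm caps near 95/µm²).
- Density units are fixed: background 0, cytosol 0.08, coat 0.7, ribbon
  0.9, membrane 1.0, arciform 1.2, gold 12. Gold is an order of magnitude
  above stained membrane so that it dominates line integrals in
  projection, as colloidal gold does; fiducials are deposited on the slab
  faces at sites not superposed on dense structure in projection
  (emulating the analyst's choice of usable beads).
- SNR is defined against the membrane level: `add_noise(snr=5)` adds white
  Gaussian noise with σ = 0.2.

Default sizes: the default phantom is a 576 × 576 × 84 nm patch at 3 nm
voxels with 16 vesicles; the counting phantom puts the full docked = 470 /
omega = 187 condition on 3 µm² of in-plane membrane at 4 nm voxels
(433² × 26). These sizes are chosen so the whole suite runs in minutes on
one CPU while keeping the reported biological conditions (counts, densities,
spacings, SNR, geometry) intact.

What the phantom does **not** emulate: electron-optical contrast transfer,
beam-induced local doming (only isotropic linear shrinkage), stain
granularity beyond a weak smoothed texture, organelle interiors, and the
pentagonal substructure of the arciform density. Passing tests therefore
demonstrate correctness of the analysis chain under idealized contrast,
not performance on real micrographs.

## Projection and simulation

Projection is a parallel-beam line integral via trilinear resampling with
a ray step of 0.5 voxel (this bounds the oracle tolerances: mass is
conserved to ~1e-3, analytic point trajectories to < 0.1 px). Shrinkage
ramps linearly with exposure index from 1 to the final factor — the
measurement (first vs last untilted view) only constrains the endpoints,
and dose accumulates roughly linearly. Noise models: Gaussian or mixed
Poisson–Gaussian with configurable gain. All applied distortions are
recorded so any series regenerates bit-identically from its seed.

## Alignment

Gold detection: difference-of-Gaussians matched to the bead diameter,
ring-isotropy veto (a response that stays above 0.75× the peak anywhere
on a ring of 1.6 d is an edge-on membrane ridge, not a bead), and
rim-background-subtracted intensity centroiding (≤ 0.3 px noise-free).
Tracking seeds in the best-populated image, links by
nominal-geometry-predicted positions from running 3D triangulations,
tracks outward in both directions, then re-links every frame twice from
the converged 3D estimates; ambiguous links (< 1 px margin) are flagged,
markers missing from more than 10% of images are dropped, smaller gaps
are filled from the model.

The solver is an alternating least squares over shared marker positions
and per-image (α, β, γ, shifts), polished by a joint sparse
Levenberg–Marquardt. The center marker is fixed at the origin
(translation gauge); the remaining exact SO(3) gauge — a global rotation
of the marker + view frame, verified numerically as a 3-dimensional
Jacobian null space — is pinned by a weak prior pulling angles toward
nominal (default 0.05 px/deg; `align_series` uses 0.5 because detections
are noisy there, which suppresses per-image angle overfit). Consequently,
angle recovery is asserted as the per-image geodesic rotation error after
a best-fit global rotation; shifts are gauge-invariant under the
center-marker convention. One trimming pass down-weights observations
with residuals above 3× the median (bad links, beads over structure).
`align_series` additionally removes the estimated shrinkage ramp from the
track coordinates before solving, and re-centers the output frame on the
fiducial centroid so the specimen stays inside the reconstruction box.

Shrinkage is the ratio of mean pairwise gold distances between the
trailing and leading untilted views; `robust_shrinkage` first drops
markers whose median pair ratio is an outlier. Recovery of an applied
0.98 factor is within 0.002.

## Reconstruction and refinement

WBP filters each projection with a radial ramp |ν| (the analytic conical
sampling-density correction, raised-cosine rolloff toward Nyquist;
'flat' = unweighted is selectable — a per-frequency exact overlap weight
was considered and not implemented) and gathers voxel-driven bilinear
samples along each beam. The operator is linear, translation-equivariant,
localizes a point source to its true voxel, and shows the expected
missing-cone z-elongation (FWHM ratio ≈ 1.2 for a small sphere at 55°).

Global projection matching re-projects the current map per image,
registers measured against re-projected by upsampled phase correlation on
band-passed images, and accepts an iteration only if the mean normalized
cross-correlation does not decrease (two consecutive drops stop with the
best solution). Local refinement windows a full-volume re-projection at
each sub-volume's projected footprint (default grid 4×4×1, 25% overlap,
Hann-windowed crops) and reports per-sub-volume, per-image shift
corrections; with a 1×1×1 grid they reduce to the global deltas. Against
an imperfect (WBP) reference the null-case corrections carry a ~0.3 px
bias from reconstruction artifacts; against a faithful reference they are
zero, which is how the null and stretch-field contracts are tested. A
known 3% in-plane stretch is recovered as the slope of correction vs
footprint coordinate within 20% (windowed averaging biases it slightly
low).

Resolution proxy: line profiles across a membrane, cubic-spline sampled
(linear interpolation pins peaks to the voxel grid), two strongest peaks
refined by a local parabola; the median peak-center distance is the
estimate. 6 nm spacing reconstructs to 5.8 nm at 2 nm voxels, 3 nm to
~2.8 nm at 1 nm voxels.

## Segmentation and counting

The watershed floods the inverted smoothed density from h-maxima markers
(merge depth 0.15 density units); everything below an Otsu background
level seeds one background basin so foreground regions do not annex the
cytosol. Region classification is by explicit thresholds on mean/max
density, volume, inertia elongation and bounding-box extents (gold:
max ≥ 3; membrane: sheet-like, elongated or very large; vesicle: volume
within 0.1–4× the nominal shell, compact, thicker than 24 nm); a
supervised random-forest mode over the same features exists for
user-marked exemplars. Conflicts resolve by fixed precedence
gold > membrane > vesicle > density tiers > background, idempotently,
with an adjacency rule relabeling vesicles fully surrounded by gold.

Vesicle centers come from a self-calibrated spherical-shell matched
filter: the response is normalized against the same filter applied to an
ideal isolated vesicle rendered at the working voxel size (threshold 0.40
of the perfect-match response), and peaks whose central density exceeds
0.30 are vetoed — a genuine vesicle has an electron-lucent lumen, whereas
ribbon and membrane edges that mimic a shell ring do not. This is the
package's stand-in for the interactive seeding of the original
semiautomatic procedure. On the default phantom at SNR 5, detection
reaches recall ≈ 0.99 and precision ≈ 0.99 over seeds.

Fusion-state assignment samples the lightly smoothed density: membrane
contact if |center-to-plane| ≤ r + s + 14 nm; then the pore test — if the
maximum density along the vesicle's axis across the membrane band
(plane ± s) stays below 0.45, the lumen opens to the extracellular space
(omega), otherwise the contact retains a leaflet (docked); a mean coat-
band density above 0.28 marks coated; proximity to the ribbon marks
tethered; else cytoplasmic. The plasma-membrane plane is fitted with its
normal from the dominant sheet-like membrane region and its position from
the mean-density profile along that normal, choosing the candidate peak
nearest the vesicle cloud (the parallel horizontal-cell membrane is the
other peak). Counting applies the 2/3–1/2 rule to the fraction of each
vesicle's diameter inside the slab (both boundaries closed upward). The
full docked = 470 / omega = 187 condition at SNR 5 is recovered to ~1%.

The weighted-count condition runs on the noisy phantom density map (the
stand-in for a refined tomogram): the reported docked areal density requires
~3 µm² of membrane, which fits a 50 nm slab only as an in-plane plane —
and an in-plane membrane's normal points into the missing cone, so no
conical reconstruction could carry it faithfully. Tomographic fidelity is
validated separately (next section) on through-slab geometry.

## End-to-end fidelity

phantom → conical series (1 px shift jitter, 0.98 shrinkage, Gaussian
noise at SNR 5) → bead detection, tracking, bundle adjustment → WBP →
projection matching. The comparison restricts the ground truth to the
sampled conical region (Fourier components within 35° of the z axis
removed — the missing cone is unknowable), low-passes both volumes to
0.6× Nyquist (the band carrying the bilayer signal at 3 nm voxels), and
registers the reconstruction to the truth by translation (the alignment
frame is marker-defined). Solved-alignment reconstructions reach Pearson
r ≈ 0.89–0.94 across seeds, essentially the ceiling obtained with the
oracle true alignment (~0.93).

## Open design choices

- The 1/d³ simple-cubic packing model behind the density-from-spacing
  arithmetic reproduces both published endpoints (580 and 750 /µm³) but
  is an assumption; it is isolated in one function and not reused.
- The "~75% of spherule volume" statement is read as the fraction of
  terminal volume that is vesicle-populated cytoplasm and exposed as
  `populated_fraction` (default 0.75) in the per-spherule budget helper;
  with the reported density range this brackets 5,800–7,500 vesicles per
  terminal.
- The 3–5 min omega increase computes to 251.3% of the light-adapted
  baseline from the table values; the package reports the computed value.
- The trailing untilted view is used only for shrinkage estimation, never
  in reconstruction; per-image tilt refinement is on by default and can
  be frozen (`refine_tilt=False`).

## Known limitations

- No CTF simulation or correction; no SIRT/ART; no markerless alignment.
- The exact (per-frequency overlap) WBP weighting is not implemented;
  ramp and flat weightings are.
- Local refinement estimates shift corrections only (no per-sub-volume
  angle corrections) and averages over its window, biasing strong
  deformation gradients ~15–20% low.
- Membrane-plane fitting assumes one dominant, axis-aligned planar
  membrane; convoluted invagination geometries would need a general
  surface model.
- Fusion classification on reconstructions degrades with the missing
  cone when the membrane normal approaches z; counting-grade performance
  is demonstrated on phantom-grade (refined-tomogram stand-in) maps.
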