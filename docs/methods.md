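# Methods

## Scope and model

`vesta` reimplements, at desk scale, the computational chain by which
cryo-electron tomography resolves the protein organization under docked
synaptic vesicles: simulate (or load) tomographic volumes of vesicles
docked to a planar presynaptic membrane, classify each picked vesicle by
view and interbilayer distance, pool the primed subset, align / classify /
average the subtomograms under missing-wedge constraints, optionally impose
Cn rotational symmetry, and quantify the averaged map (interface peak
count, ring diameter, membrane gap, FSC resolution).

Because the real neuronal tomograms cannot be regenerated on a desk, the
package ships a first-class synthetic-scene generator whose defaults encode
the study population, and every pipeline stage is validated by parameter
recovery against the generator's ground truth.

## Synthetic scenes

A scene is a parametric phantom rendered on a voxel grid (positive
protein/lipid contrast, zero background — the deposited-map sign
convention, so peak detection finds maxima):

* **Vesicle** — spherical bilayer shell. The *diameter* follows the
  bilayer-peak convention used by the measurements: diametric mid-surface
  center-to-center distance plus one 5-nm average bilayer thickness, so a
  vesicle of diameter *D* has mid-surface radius (*D* − 5)/2. Cohort
  diameters are truncated-normal, default 43.88 ± 5.32 nm.
* **Presynaptic membrane** — planar 5-nm slab. The interbilayer gap *g*
  places its mid-plane at center-to-center distance *g* + 5 nm from the
  vesicle mid-surface along the docking axis. The docking mixture defaults
  to 75% primed (gap uniform in 2–5 nm, mean at the reported ~3.5 nm; the
  source study constrains the primed pool only to ≤ 6 nm, so the
  within-pool law is a package choice) and 25% tethered (uniform 8–20 nm).
* **Interface ring** — *n* rod-like densities (default 6) with axes along
  the docking axis, spanning from the membrane mid-plane to the local
  vesicle mid-surface, centers equally spaced on a circle of diameter
  (ring_outer_diameter − rod radial extent); defaults 38-nm outer ring and
  2 × 4-nm nominal rod cross-section put the planted peak-center circle at
  36 nm. The ring phase is uniform-random per vesicle. Rod cross-sections
  are rendered band-limited (Gaussian, σ floored at 0.8 voxel): the
  nominal widths are below the bin4 voxel size, and a hard-edged
  sub-Nyquist feature voxelizes with a lattice-dependent apparent position
  error of up to half a voxel, which would corrupt ring-radius recovery.
* **Tethers** (tethered scenes) — 2–5 thin disordered rods at random
  azimuths bridging the gap; no ring.
* All components get a 1-voxel linear soft edge. A full σ = 1 voxel
  Gaussian would merge the two 5-nm bilayers at primed gaps into a single
  unresolvable peak, so the ramp width — not σ — is one voxel.

Views: *side* (membrane normal in the beam-perpendicular plane, random
azimuth) or *top/bottom* (normal along the beam, random sign), mixed at
the study's observed side fraction (2556/7527) by default.

Imaging is an ideal single-axis scheme: the specimen rotates about *y*
over ±51° in 3° steps (35 projections), each projection is the exact line
integral along the beam, and white Gaussian noise is added per projection
at variance = signal variance / snr. No CTF or dose model: the source data
were recorded with a Volta phase plate (near-ideal phase contrast) and the
analysis under test is geometric, not optical. Default pixel size is
21.6 Å — the bin4 scale at which the original picking and classification
were done; default boxes are 64³ voxels (~138 nm).

## Reconstruction

`tomo` provides weighted back-projection (ramp filter along the detector
axis, per y-slice exact for single-axis geometry) and SIRT with standard
row/column ray-length normalization,

    x ← x + relax · C⁻¹ Aᵀ R⁻¹ (b − A x),

default 30 iterations, relax 1.0 (the source names SIRT without
parameters; these are engineering defaults). Updates are confined to the
inscribed cylinder in the tilt plane, since voxels outside it rotate out
of the field of view and are never consistently sampled; the data residual
is checked for monotone decrease and reconstruction aborts on growth
beyond 1.1×. The cohort generator reconstructs with WBP by default: SIRT
at production quality costs ~20 s per 64³ subtomogram and would put the
synthetic cohorts out of desk reach, while every distance/diameter
estimator was verified to behave identically on both reconstructions.
Rotations use cached bilinear gathers (linear interpolation); sub-voxel
shifts use Fourier phase ramps.

## Census

* **View classification** scans candidate in-plane membrane normals
  (15° grid, refined at 2.5°). The profile for each direction bins only
  voxels far from the central axis, so the centered vesicle cannot shape
  it: a planar membrane fills every slab and stands out of the noise
  (threshold: 8 median-absolute-deviations above the profile median). A
  membrane normal along the beam is erased by the missing wedge, so a
  detectable vesicle shell without any in-plane slab means *top/bottom*;
  featureless volumes return *unknown*, never an exception.
* **Distances.** The center-to-center distance is read from an
  interpolated 1D profile along the docking axis (0.25-nm steps, averaged
  over in-plane lateral offsets only — offsets along the beam would sample
  the wedge-smeared part of the curved shell). Bilayer peaks are localized
  as the centroid of the contiguous region above half height: bilayer
  profiles are flat-topped, so a parabolic vertex is quantized by the
  voxel lattice while the centroid is lattice-phase invariant. When the
  two bilayers merge into one plateau (gap ≈ 0) the separation is
  inferred from the plateau's half-max width (width = c2c + 5 nm for slab
  profiles). Interbilayer distance = c2c − 5 nm; diameter = diametric
  peak-to-peak + 5 nm (median over 12 in-plane azimuths, robust to the
  few profiles that cross the membrane in side views).
* **Shell-radius corrections.** Two deterministic corrections are applied
  to spherical-shell peaks: the analytic lateral-averaging curvature term
  ⟨ρ²⟩/(2r), and a wedge-PSF calibration — shells reconstructed from a
  limited tilt range appear 0.3–0.7 nm too small at the equator because
  wedge-lost shell sections smear along the beam and deposit density just
  inside the ring. The calibration reconstructs analytic reference shells
  through the same simulate/reconstruct path once per acquisition
  geometry and interpolates the apparent-to-true shift, exactly as
  magnification or CTF calibrations are applied; it derives from the
  acquisition geometry only.
* **Gating.** Interbilayer ≤ 6 nm → primed, ≥ 8 nm → tethered (both
  boundaries inclusive; the source states the pools without resolving
  inclusivity), strictly between → *intermediate*, excluded from both
  pools rather than silently dropped. The homogeneous-diameter gate keeps
  |diameter − 43.88| ≤ 5.32 nm (±1 SD window), both parameters exposed.

## Subtomogram averaging

All particles are brought into the **docking frame**: the axis from the
vesicle center to the membrane contact point (the picked coordinates, as
the study initializes poses) maps onto +z and the docking midpoint lands
on the box center. Euler angles are ZYZ, intrinsic, degrees; shifts in
voxels apply after rotation.

Every particle carries an analytic **wedge mask** (single-axis wedge about
y) whose orientation composes with every pose; masks are Hermitian by
construction (the ±Nyquist ambiguity of even grids is resolved
conservatively). The **constrained cross-correlation** between two volumes
is the normalized Fourier inner product restricted to the intersection of
their wedge masks, DC term removed — verified against a direct-space
brute-force oracle to 1e-6.

**Alignment by classification.** Spin (ring-phase) alignment of a single
noisy particle against a smeared reference is hopeless, so the first
reference is seeded by classification: PCA (8 components) on the
interface-focus voxels of the wedge-filtered, initially posed particles,
Ward-linkage agglomerative clustering (10 classes by default — the
original 200 classes on 7,527 particles scale to cohorts of ~100), and the
class average with the strongest azimuthal structure in the interface
annulus becomes the reference. Rounds then alternate batch spin alignment
(shared rotated-reference FFTs; global 6° grid first, then local ±12° at
3°) with wedge-compensated re-averaging, stopping when the mean
constrained CC improves by less than 0.001. Alignment is scored inside a
cylindrical interface focus mask (radius 25 nm, half-height 6 nm) on
volumes low-passed to 4.5 nm: the focus removes the spin-invariant
membrane mass, and the low-pass removes both noise and the
rotation-angle-dependent interpolation attenuation that would otherwise
dominate the score surface. The spec'd ±15°/5° cone search is implemented
in `align_one` but the desk schedule fixes the axis from the
initialization (a full cone multiplies cost ~37× and recovers nothing
when axes come from picked coordinates). Shift search over the
constrained-CC map is available; the desk schedule uses radius 0 because
the synthetic picks are exact.

**Averaging** accumulates rotated spectra and rotated wedge coverage and
divides by coverage (floored at one count, no Wiener term); voxels never
covered are reported as a fraction with a warning above 20%. **Cn
symmetrization** averages the n in-plane rotations of the map about the
docking axis; it is idempotent up to interpolation tolerance and never
increases rotational variance.

## Map metrics

The interface plane is the midpoint between the two bilayer peaks on the
central z profile. Before peak detection the plane's rotationally
symmetric component (the angular mean at each radius, from interpolated
polar sampling) is subtracted: the radially sloping vesicle-tail
background would otherwise pull sub-pixel peak positions ~0.5 nm inward.
Peaks are then local maxima of the residual above its annulus median +
3 robust SD (1.4826 × MAD — the peaks are sparse outliers of their own
annulus and must not inflate the threshold; annulus 10–25 nm, bracketing
the ~19-nm reported peak radius), with greedy non-maximum suppression at
6 nm. Sub-pixel positions come from radial- and tangential-profile
centroids in polar coordinates with cubic-spline sampling: per-axis
parabolas are biased for tangentially elongated peaks at azimuths oblique
to the lattice. The *ring diameter* is twice the mean peak radius
(peak-center convention; the outer-edge circle is larger by one rod
radial extent — with the default 2-nm rods the planted peak-center circle
is 36 nm against the 38-nm outer ring). The membrane gap reuses the
census bilayer-peak rule on the z profile. The symmetry order maximizes
the radially averaged angular power spectrum over orders 1–12. FSC uses
unit-voxel shells to Nyquist with linear threshold interpolation,
threshold 0.5 by default (0.143 available); half-sets split even/odd.

## Acceptance surface

`scripts/acceptance.py --seed S --out f.json` regenerates everything from
scratch: the primed-pool refinement (n=120, snr 0.5) for the C6 ring
diameter and the membrane gap, the n=500 side-view distance
classification for the primed percentage, and the n=300 top/bottom cohort
for the mean diameter. Problem sizes are the package's desk-scale study
conditions; the full-study scale (256³ boxes, 7,527 particles, 200
classes) is deliberately out of scope.

## What passing tests do and do not show

The generator reproduces the *geometry and statistics* of the study
population and the *sampling physics* of single-axis tomography (missing
wedge, anisotropic PSF, projection noise). It omits: electron-optical
physics (CTF, dose damage, detector MTF), cytoplasmic clutter, membrane
deformations and non-spherical vesicles, picking errors (centers and
contact points are exact), and tilt-series misalignment. Parameter
recovery here therefore demonstrates that the analysis chain is correct
and unbiased under the stated forward model — not that it would segment
real neuronal tomograms unaided.

## Numerical choices and degenerate inputs

Linear interpolation everywhere (rotations) with exact fast paths for
multiples of 90°; Fourier phase shifts for translations; float32 volumes.
Ties in alignment break to the earliest grid rotation and smallest flat
index. Empty masks, flat volumes, unresolvable profiles and empty classes
raise typed errors or are flagged per record, never silently dropped;
`classify_view` returns *unknown* instead of raising. Ward clustering and
full-SVD PCA make classification deterministic given input order; all
cohort randomness derives from one seed via spawned `SeedSequence`s.
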