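# Methods

`catchquant` re-implements, as a tested library with seeded synthetic
inputs, the quantitative analyses used to characterise directional catch
bonding between the vinculin tail domain (Vt) and F-actin: contact mining
of constant-force pulling trajectories on the simulation side, and the
FRET-tension-sensor imaging pipeline (efficiency maps, adhesion
morphometrics, intra-adhesion tension gradients, photobleaching recovery,
stress-fiber coalignment) on the cell side.  This note records the models,
the defaults and why, what the generators do and do not emulate, and the
numerical choices made where the underlying procedures were open.

## Contact analysis of pulling trajectories

**Hydrogen bonds.** A donor-H...acceptor bond is detected when the
donor-acceptor heavy-atom distance is <= 3.5 Å and the deviation from
linearity, measured at the donor as the angle between the D→A and D→H
vectors, is <= 30°.  Donor/acceptor roles come from the topology (N and O
heavy atoms with an attached hydrogen donate; N/O accept); no protonation
inference is attempted.  Only intermolecular pairs (Vt vs. actin) are
considered.  Occupancy is the percentage of frames in which a residue pair
satisfies the criterion, pooled over replicates at each
(force, direction); zero-occupancy rows are not materialised.

**Native fraction.** Native bonds are those detected in the unloaded
reference structure.  The fraction maintained under load is
N_persistent / N_total with a configurable persistence threshold
(default: any nonzero occupancy counts as maintained, since the underlying
wording — bonds "maintained throughout" — names no cutoff).

**Lifetime and force response.** Bonds are long-lived at >= 40% occupancy,
medium in [20%, 40%), short below 20%, using the bond's maximum occupancy
inside the analysis force window (default 124–132 pN, the dissociation
window; the class could alternatively be assigned per force — the
per-window maximum best captures "long-lived" and is the configurable
default).  A bond strengthens in a direction when its occupancy at a window
force exceeds the baseline occupancy by more than a factor 1.1 (weakens for
the reciprocal).  The baseline is the unloaded (lowest simulated force)
state by default; chaining to the nearest lower simulated force is
available (`baseline="previous"`).  The unloaded baseline is the primary
reading of "from their unloaded state or previous low force applied state"
and is far more robust when occupancy estimates carry frame-sampling noise.
Ratios are only evaluated when at least one of the two compared occupancies
reaches a detectability floor (default 10%): a 1.1x ratio between two
noise-floor occupancies measures sampling fluctuation, not force response.
A DAFS (directionally asymmetric force-strengthening) bond strengthens in
the pointed direction and in neither of the other two.

**Interface metrics.** Salt bridges: opposite-charge flagged side-chain
atoms on opposite molecules within 3.2 Å, counted per residue pair.  Van
der Waals contacts: intermolecular residue pairs with minimum heavy-atom
distance within 5 Å.  Buried interface area:
SASA(Vt) + SASA(actin) − SASA(complex) by Shrake–Rupley (probe 1.4 Å,
960 sphere points, element-based radii), computed with biotite.

**Force conversion and batch arithmetic.** Discrete pulling applies an
energy jump dE per distance step dR; the force is (dE/dR) scaled by
69.477 pN per (kcal/mol/Å) (thermochemical calorie, CODATA Avogadro
number), so the canonical 0.015 kcal/mol jump per 1 Å step is ~1 pN.  The
batch planner enumerates an inclusive force grid: 0–150 pN at 1 pN, three
directions, ten replicates gives 151 x 3 x 10 = 4530 runs.

**PMF binding energy.** ΔG is the unbound plateau (mean over the last 10%
of the reaction coordinate, configurable) minus the global minimum; the
estimate is invariant to constant energy offsets and requires a strictly
increasing coordinate.

**Superposition.** RMSD after least-squares rigid superposition (Kabsch via
SVD with a determinant guard against reflections) over a supplied Cα
pairing; at least three pairs are required.

## Sensitized-emission FRET

Channels: donor excitation/donor emission (I_d), donor excitation/acceptor
emission (I_f), acceptor excitation/acceptor emission (I_a).  Preprocessing
subtracts dark frames, flattens by the mean-normalised flat field,
registers donor and FRET channels to the acceptor channel by integer-pixel
cross-correlation (translation only; shifts beyond 10% of the image fail),
and subtracts a background median taken from a user mask or the four image
corners.

Bleed-through coefficients come from single-fluorophore samples:
d_bt = I_f/I_d binned by donor intensity, a_bt = I_f/I_a binned by acceptor
intensity, per-bin medians summarised by an intensity-weighted mean.  The
scalar summary is applied pixelwise by default; nearest-bin or linearly
interpolated intensity-dependent application is available (the binned
source procedure does not state an interpolation rule).  The corrected
signal is F_c = I_f − d_bt I_d − a_bt I_a.  The G factor comes from two
fusion constructs of constant efficiency as −Δ(F_c/I_a)/Δ(I_d/I_a).
Efficiency is E = (F_c/G)/(I_d + F_c/G); negative F_c pixels are clamped to
zero rather than masked, which keeps near-zero-efficiency statistics
unbiased instead of truncating the noise distribution (configurable), and
pixels with a non-positive denominator are masked.

## Adhesion morphometrics and classification

**Segmentation** (the cited "water algorithm" names no parameters, so the
procedure here is a design choice): difference-of-Gaussians enhancement
(σ 1.5/8 px), hysteresis thresholding against robust in-cell background
statistics (median + 4/8 MAD), marker-based watershed with h-maxima markers
(suppression depth 30% of the foreground dynamic range) so that touching
adhesions with distinct peaks split while plateau noise does not, and a
minimum-size filter (9 px ≈ 0.1 µm² at 108 nm/px).  The cytoplasm mask is
the in-cell complement of the adhesion mask dilated by a disk of radius
10 px — one reading of a "scale factor of 10" dilation, configurable.

**Equivalent-ellipse moments.** Second-order central moments of each
adhesion's binary pixel set (intensity-free: the equivalent ellipse of a
blob) are area-normalised; axis lengths are scaled so that `fa_major` /
`fa_minor` equal the *full* axis lengths of the equivalent ellipse
(4·sqrt(eigenvalue); this matches the common region-property convention and
makes a rendered 30-px ellipse read back as 30 px).  Axis ratio and
orientation are unaffected by the normalisation.  Orientation applies the
arctangent to the standard moment quotient, branching on sign(u20 − u02)
for conditioning; circular regions are flagged degenerate with orientation
0.  All orientations are axial (180°-periodic) and folded to (−90°, 90°].

**Context features.** Relative orientation subtracts the cell's axial mean
adhesion orientation (double-angle averaging; a plain arithmetic mean of
axial angles can cancel).  Radial orientation compares each adhesion's
orientation with the direction from the cell centroid — the mean of
adhesion centroids, matching the centroid convention used by the spatial
variation index; a cell-mask centroid is a reasonable alternative and can
be supplied by the caller.  d4FA is the mean distance to the four nearest
adhesion centroids (fewer, flagged, in sparse cells).  Normalised distance
from the cell edge is d_edge/(d_edge + d_centroid) via a Euclidean distance
transform of the cell mask: 1 at the centroid, 0 on the boundary.

**Maturity.** A depth-4, seeded decision tree over six features (area, axis
ratio, d4FA, relative and radial orientation, edge distance) separates
protrusion-associated from stress-fiber-associated adhesions.  The original
training data are not published, so the tree here is trained on labelled
(synthetic or user) data; the synthetic two-population feature generator
draws SF-like adhesions as large/elongated/sparse/radial/interior and
PR-like as small/round/dense/edge-proximal.

## Intra-adhesion tension

Line profiles sample the efficiency (and acceptor) map along the adhesion's
major axis at 1-px steps, band-averaged across half the minor-axis length,
and are smoothed with a cubic smoothing spline whose parameter defaults to
generalised cross-validation (no smoothing parameter is stated anywhere).

The spatial variation index compares the inverse-efficiency-weighted
centroid (tension sensors report load as *reduced* FRET, so weights 1/E
shift the centroid toward high tension) with the geometric centroid, both
as distances from the cell centroid, normalised by the adhesion's major
axis length.  Positive SVI means tension skewed away from the cell centre.
The "FRET index" being inverted is taken to be the measured efficiency.
Non-positive efficiencies are floored at 1e-3 by default (exclusion is
available but biases dim adhesions).  The index is computed literally from
the distance difference, so purely tangential skew can contribute; a
projection onto the radial axis would be an alternative reading.

## Photobleaching recovery

The bleached-adhesion trace is divided by its pre-bleach mean and then by
the unbleached-adhesion control normalised to its own pre-bleach mean; a
shared global acquisition-bleach decay cancels exactly in this double
ratio.  The cytosol control is carried but unused by the default pipeline.
The normalised curve is fit to R(t) = R_f − (R_f − R_0) e^(−kt) by bounded
multi-start nonlinear least squares (5 seeded starts; bounds R in [0, 1.5],
k in (1e-5, 10) /s; best residual wins, so the fit is deterministic for
given data), with τ½ = ln 2 / k.  Flat curves are flagged unidentifiable
(τ½ = NaN).  R_f is reported as the mobile-fraction proxy;
(R_f − R_0)/(1 − R_0) is also returned for the alternative convention.
On the 5 s x 5 min sampling schedule, recovered half-times are mean-unbiased
within 2% up to τ½ ≈ 60 s; substantially slower recoveries (τ½ beyond about
a quarter of the observation window) acquire a right-skewed τ½ distribution
because k trades off against R_f near the bound — a protocol identifiability
limit, not a fitting defect.

The tension-sensitivity regression is ordinary least squares of per-adhesion
τ½ on efficiency, reporting the slope, its standard error and the F-test
p-value against the zero-slope model; a negative τ-vs-E slope (longer
residence under higher load) is the signature of tension-stabilised
exchange.

## Stress fibers and coalignment

The structure tensor is built from Gaussian-derivative gradients (σ_g =
1 px) with Gaussian tensor averaging (σ_t = 2 px).  The tensor's dominant
eigenvector points along the intensity gradient — *across* a fiber — so the
reported θ_SF is the structure axis perpendicular to it, folded to
(−90°, 90°]; this is what makes a stripe pattern at angle φ read back φ.
The dominant eigenvalue l1 (gradient energy) thresholds the fiber mask
(default: 75th percentile of positive l1).  The per-cell orientation spread
is the RMS axial deviation about the double-angle axial mean; when the
axial resultant vanishes (perfectly balanced orthogonal populations) the
reference orientation is chosen to minimise the RMS deviation, giving 45°
for equal 0°/90° populations rather than an arbitrary value.  A naive
linear SD would behave similarly on folded angles but is discontinuous at
the fold; the axial convention is the default and the output records it.

Coalignment partitions the cell into nearest-centroid (Voronoi) regions of
the adhesions on the pixel raster (regions exactly partition the cell
mask).  Per region: fiber density as percent mask area, the axial mean of
masked fiber orientations (double-angle averaging — the source computes "a
single vector per region" without stating the rule for axial data), and
θ_Rel = |θ_SF − θ_FA| folded to [0°, 90°], since an unfolded absolute
difference would be discontinuous at the axial wrap.  Regions without fiber
pixels are excluded from the cell mean with their count reported.

## Synthetic data: what it does and does not emulate

All generators are seeded and bit-reproducible; identical spec + seed gives
identical artifacts.

*Trajectories* place each planted bond's donor-H-acceptor triad either well
inside the detection criterion (2.9 Å, collinear) or far outside it (6 Å),
frame by frame, with exact quota placement — round(occupancy x n_frames)
present frames at seeded positions — so realised occupancy equals the
request without Bernoulli noise and classifier tests are deterministic.  An
optional frame-flip probability re-introduces detection noise.  Triads are
spaced 30 Å apart; there is no force field, no actual dynamics, and no
coupling between bonds — the geometry exists purely to drive the detector.

*FRET scenes* invert the sensitized-emission equations: with per-pixel
expression X and true efficiency E, the noiseless channels are I_a = X,
I_d = X(1−E) and I_f = G·X·E + d_bt I_d + a_bt I_a, so the analysis
round-trips to machine precision without noise.  Adhesions are filled
ellipses with a flat-top super-Gaussian falloff (a `SceneSpec` states full
ellipse axis lengths); an optional efficiency ramp along the major
axis plants tension gradients.  Matching donor-only/acceptor-only scenes
carry pure bleed-through for calibration, and constant-efficiency scenes
stand in for the G-factor fusion constructs.  Noise is Poisson shot noise
plus Gaussian read noise (default sd 3 counts at ~8000-count adhesion
peaks, i.e. roughly 1–2% pixel noise).  Real images differ in ways the
generator does not model: non-uniform illumination residuals, registration
error beyond integer shifts, fluorophore maturation differences,
out-of-focus light and motion.  Passing round-trip tests therefore
validates the *algebra and the estimator chain*, not robustness to every
microscope artifact.

*Actin scenes* are parallel stripe bundles (angle, thickness, target areal
coverage; realised coverage is recorded) rendered globally or per adhesion
Voronoi region, lightly blurred; there is no fiber curvature, crossing
statistics or sarcomeric structure.

*Recovery series* follow the single-exponential model times a global decay
shared with the control region, plus Gaussian noise — no reaction-diffusion
kinetics and no two-component exchange.

*PMF fixtures* are Morse-shaped wells of prescribed depth rising to a flat
plateau, optionally jittered; they test the ΔG extraction rule, not any
sampling physics.

## Study conditions and problem sizes used by the checks

The packaged checks run at sizes chosen to exercise every code path with
tight statistics: 50 scenes of 200x200 px with ~6 adhesions each for the
efficiency round-trip (the unloaded-sensor ground truth of 28.6% with
d_bt = 0.6, a_bt = 0.2 and default noise reads back within ±0.5 percentage
points); the planted DAFS study uses ten bonds, forces {0, 124, 128, 132}
pN, ten replicates of 50 frames (the caller is exact noiselessly and holds
precision/recall >= 0.95 under 5% frame flips over 20 seeds); recovery
fitting is validated over R_f in {0.6, 0.8, 1.0} x τ½ in {10, 30, 60} s at
noise sd 0.02 with 100 replicates per cell.

## Known limitations

- The DAFS force-response rule is a threshold on occupancy ratios;
  occupancies near the detectability floor are excluded rather than
  modelled, and no multiple-comparison control is applied across bonds.
- The maturity classifier ships untrained; synthetic feature distributions
  are stylised and a tree trained on them will not transfer to real cells.
- Conversion of FRET efficiency to piconewtons requires an external sensor
  calibration; the pipeline stops at efficiency (a pluggable lookup can be
  applied downstream).
- Registration is translation-only; rotation/scaling misalignment is out of
  scope.
- The raster Voronoi tessellation assigns pixels by Euclidean distance to
  adhesion centroids; geodesic distance within concave cells is not used.
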