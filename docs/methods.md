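# Methods

## Coordinate and pose conventions

Right-handed frame; the procentriole cylinder axis is +z with the proximal
end at z = 0 and +z pointing to the microtubule plus end (distal). Lengths
are nm, angles degrees. Triplets are indexed 1–9 counterclockwise viewed
from the distal end; PFs are 1-based (A1…A13, B1…B10, C1…C10). Euler angles
are zyz intrinsic; a pose (φ, θ, ψ) plus shift maps the canonical reference
onto an observation. Volumes are indexed (z, y, x); rotations about the box
centre use the (N−1)/2 convention so that array-centre rotations coincide
with rotations about the modelled axis.

## The geometric model

Each blade is a rigid cross-section placed at the tip of a radial spoke
(pivot radius = hub radius + spoke length, default 11 + 70 nm) and rotated
in-plane by the blade angle θ(z). The A-tubule is a closed 13-PF ellipse
(semi-axes 11 × 9.5 nm, ≈5 nm inter-PF arc spacing); B and C are open 10-PF
arcs whose centres are offset along the blade axis (17, −4) nm from their
inner neighbour. These cross-section parameters come from canonical MT
lattice spacing; they are configuration, not measurement.

Twist is modelled linear in z: θ(z) = θ₀ + r·z. The observed motion is
progressive but no functional form is established, so linearity is the
simplest adequate profile, and the rate r is a free parameter (default
0.12°/nm, chosen so that the blade angle advances ~11° over the 90 nm
analysis span — within the ~10–16° swing the conformational classes span).
Positive r means the blade angle grows counterclockwise viewed from distal,
i.e. left-handed chirality with the thumb towards the plus end; mirroring
the model through any plane containing z flips the realised sense (the
`mirrored` flag) and therefore the handedness. The luminal diameter is
defined as twice the minimal axis-to-A-wall distance; with the pivot fixed
it grows monotonically with θ, producing the iris-diaphragm opening.

## Synthetic data

PF walls are rendered as continuous Gaussian tubes (σ = 1.2 nm), sampled
axially every 1 nm with a cosine modulation of depth 0.6 at the 4 nm
monomer repeat. Decorations (pinhead on A3, a 45 kDa lumen cone on A5) are
isotropic blobs repeating at 8 nm. Rendering is additive and nonnegative;
a twist-free model is 9-fold rotationally symmetric by construction.

The missing wedge zeroes Fourier coefficients whose direction in the kx–kz
plane lies more than the tilt range (default 60°) from the kz axis — the
geometry of a tilt series about y with the beam along x. The operator is an
orthogonal projection (idempotent, norm non-increasing) and preserves
Hermitian symmetry.

Subtomograms are boxed per segment (29 nm, more than three of the largest
8 nm repeat), centred on the A-tubule. Segment centres snap to the 8 nm
lattice: a real pipeline registers particles onto the axial repeat through
the shift search, so ground-truth shifts are sub-repeat jitter (uniform
±1.5 nm) rather than arbitrary lattice phases. The canonical reference is
the same triplet with blade angle zero at the segment centre and the
model's twist retained inside the segment, so a record's pose is exactly a
rotation by φ = azimuth + blade angle: reference and observation are pieces
of one helical lattice. Noise is additive Gaussian calibrated to the
requested variance-ratio SNR inside a dilated signal mask (background-
dominated boxes otherwise make a whole-box SNR meaningless); it is added
after wedge filtering. No CTF is simulated.

Assembly intermediates are assigned per filament: with probability
`b_partial_fraction` (`c_partial_fraction`) a filament carries an
incomplete B (C) region, placed according to a positional mix whose default
is the five-class distribution observed for B intermediates
(28.7 / 25.5 / 33.8 / 7.0 / 5.1 % for proximal end / distal end / nascent /
short / mid; the printed percentages sum to 100.1 % and are renormalised).
Incomplete B-tubules render only PFs B1–B3 (outer A-B junction); incomplete
C-tubules only C1–C3 and C8–C10 (both B-C junctions). A "short" (< 10 nm)
tubule leaves every segment of its filament without a complete tubule; the
generator labels segments accordingly, and each record stores the extents
from which its positional class is recomputable.

What the generator does not emulate: CTF, dose and detector effects,
filament curvature away from a straight axis, inter-procentriole
variability of the cross-section, and crowded neighbouring structures.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under controlled conditions, not performance on raw
experimental tomograms.

## Alignment and averaging

Similarity is a Pearson correlation of Fourier coefficients restricted to
the intersection of the two volumes' sampled (non-wedge) regions, DC
excluded. Alignment is a deterministic in-plane grid search (translations
solved per rotation from the masked FFT correlation map, bounded by a
maximum shift) followed by Nelder–Mead refinement of (φ, dx, dy, dz);
refinement is accepted only if it does not lower the score. The search is
restricted to a window around the pose predicted by filament continuity
(full circle only for the first segment of a filament). A
maximum-likelihood engine is deliberately replaced by this deterministic
constrained-correlation search: the filament-constraint and classification
layers are agnostic to the engine, and determinism makes the pipeline
testable at desk scale.

Averaging applies inverse poses (Fourier phase shifts, then linear-
interpolation rotation), masks each record's spectrum by its rotated wedge
support — interpolation leaks ~30 % of spectral energy outside the support,
which would otherwise survive normalisation as structured artefacts — and
normalises per Fourier voxel by the summed support. Half maps split by
record-index parity (the even/odd rule is a package decision).

## Filament constraint (RANSAC)

Each of the six pose parameters is regressed independently on arc length
per filament. Angles are unwrapped first; mod-360 jumps would otherwise
break the regression. The model family is polynomial with default degree 1
(linear matches the progressive twist; the degree is exposed). Minimal
subsets of size degree + 1 are drawn for a fixed 1000 iterations
(vectorised Vandermonde solve; fixed iteration count keeps runs
deterministic for a given seed); the consensus with the most inliers (ties
broken by inlier RMS) is refit on its full inlier set. Default inlier
tolerances: 2° for angles, 1.5 nm for shifts; minimum inlier fraction 0.5.
Outliers in any parameter are replaced by the per-parameter prediction;
inliers pass through bitwise unchanged. Filaments with fewer than
degree + 2 points are skipped with a status, and a filament with no
admissible consensus is flagged failed with no correction. Fitting on a
rotation-manifold parameterisation instead of unwrapped Euler angles is a
known alternative; with the filament geometry used here (pure in-plane
rotation) the two coincide.

## Classification

Heterogeneity detection is a hard-assignment k-means with wedge-aware
scoring. Class averages are wedge-normalised averages of the
inverse-transformed members in the reference frame. Scoring is forward:
the class template is rotated into each record's own frame, wedge-filtered
there, and compared in the record's native frame — so the wedge anisotropy
is identical on both sides and cancels instead of masquerading as
heterogeneity. Three numerical choices matter and were adopted after the
naive variants demonstrably failed on labelled simulations:

* **Amplitude-calibrated least-squares assignment.** Plain correlation
  argmax is biased towards lower-norm templates when classes nest (an
  incomplete tubule is a subset of a complete one): the shared density term
  is divided by a larger norm for the fuller template. Each record instead
  estimates a global amplitude α against the mean template and minimises
  ‖v/α − t_j‖².
* **Leave-one-out class averages.** At the symmetric saddle (all averages
  equal) a record's own noise inside its class average anchors it to its
  current class; excluding the record when scoring it removes the anchor.
* **Focus compositing.** For focused classification the templates share
  the global average outside the focus mask and differ only inside it, so
  the wedge point-spread bleed of surrounding density is identical across
  templates. Masking the average *before* wedge filtering (the obvious
  alternative) creates template-observation bleed mismatches that
  systematically favour emptier classes.

Initialisation: with a focus mask, records are first split by a 1D k-means
on their amplitude-calibrated focus-region occupancy (how much of the
global average's focus density each record carries) — a coarse but
label-relevant axis that the iterations then sharpen; without a mask the
split is seeded randomly. Emptied classes are re-seeded from the
worst-fitting member. Everything is deterministic given the seed.

Positional mapping of intermediates: *short* if the tubule extent is under
10 nm; *nascent* if every segment of the filament's tubule is incomplete;
*proximal/distal end* if the segment lies within one segment length
(29 nm, the default end window — the analysis cannot localise an
intermediate more finely than its box) of the tubule minimum/maximum z;
otherwise *mid*. Mid-located partial tubules are reported as such without
adjudicating between true defects and classification errors. The
reciprocal A-C linker schemes re-centre the alignment origin on the A- or
C-tubule before classification; classes below 5 % of N (configurable) are
flagged excluded. Composite linker maps dock the two half-linker averages
into a low-resolution class average by translation search and take the
voxel-wise maximum, refusing to composite below a fit-score threshold.

## Quantification

* Weighted twist: T_i = Σⱼ θⱼ N_ij / Σⱼ N_ij per longitudinal point
  (default six points over 90 nm); undefined where all counts vanish.
  Swing range is max(θ) − min(θ).
* FSC: shell width one Fourier voxel, no masking or phase-randomisation
  correction — the bare gold-standard curve; resolution is the reciprocal
  of the first crossing below 0.143, linearly interpolated; a curve that
  never crosses reports the Nyquist limit.
* Periodicity: the masked volume is averaged into a 1D axial profile,
  cropped to the masked span, Hann-tapered (the finite extent otherwise
  leaks broad low-frequency power), zero-padded for fine frequency
  sampling, and the dominant power-spectrum peak between 2 and 20 nm is
  reported (the range excludes box-length artefacts).
* MIP segmentation: difference between an average map and the co-registered
  tubule-model density, thresholded at background mean + 3 SD (background =
  outside a dilated model mask; the threshold is exposed because no
  canonical value exists), 26-connected components of ≥ 5 voxels; mass =
  0.849 Da/Å³ × volume exactly. Masses are reported only for closed
  components; unbounded filamentous densities have no meaningful volume.
* Tubule lengths: extent from first to last supra-threshold density along a
  filament trace; per-tubule mean, SD and n.

## Pipeline and problem sizes

The staged pipeline records a manifest (inputs, outputs, seed, SHA-256
checksums) per stage and a count ledger that pools source dataset counts
and subtracts per-tubule exclusions. The default demo runs 9 filaments of
100 nm at SNR 0.5 in a 40³–48³ box at 1 nm/voxel — sizes chosen so a full
run completes in about a minute on one CPU while every stage remains
statistically meaningful (tens of segments per quantity). Labelled
classification experiments use 24–100 segments; the RANSAC recovery
experiment uses 30 filaments × 12 segments.

## Known limitations

* The alignment search is in-plane (φ + shifts) around the filament prior;
  full out-of-plane search is supported by the grid but not exercised, as
  the generator produces in-plane poses.
* The wedge support of a rotated record is computed geometrically; the
  additional spectral spread of interpolation is handled by support
  masking, not modelled.
* Classification accuracy on records whose discriminating density falls
  largely inside the missing wedge is physics-limited; the engine recovers
  what the surviving in-plane directions carry.
* The twist profile is linear; curvature of the twist along z would bias
  the recovered rate towards its mean slope.
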