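# Methods

`painface` implements a dynamic facial-representation pipeline for automatic
infant pain assessment: per-frame geometric and texture measurements are
turned into per-video temporal descriptors, embedded with supervised
locality preserving projections (SLPP), classified per feature stream with
an SVM, and fused by confidence-weighted majority voting under
leave-one-subject-out (LOSO) evaluation. This note records the model, the
conventions the pipeline fixes where the method leaves them open, and what
the synthetic cohorts do and do not establish.

## Frame-level measurements

All geometry is defined on the common 68-point facial annotation (jaw
0–16, brows 17–26, nose 27–35, eyes 36–47, mouth 48–67), in pixel
coordinates with the origin top-left. "Left"/"right" denote the subject's
anatomical side (anatomical left appears at larger image x for a subject
facing the camera).

**Deformation distances (11).** Eyebrow–eye (`d_ebl`, `d_ebr`), eyelid
opening (`d_el`, `d_er`), eyebrow–mouth (`d_mbl`, `d_mbr`), eye–mouth
(`d_eml`, `d_emr`), nose–mouth (`d_nm`), mouth width (`d_mw`) and height
(`d_mh`). These track the pain-relevant facial actions of the neonatal
coding systems: brow bulge, eye squeeze, and horizontal/vertical mouth
stretch.

**Pose distances (8).** Left/right face boundary to brow, eye, nose and
mouth (`d_bb*`, `d_be*`, `d_bn*`, `d_bm*`). Lateral head shake shifts the
boundary relative to the inner components and appears as an antisymmetric
left/right change; no 3-D orientation angles are estimated.

Each distance is the Euclidean distance between the **centroids** of two
configured landmark groups. The method names component pairs but not point
pairs; centroids are robust to single-point jitter and fully determined by
the mapping file (`facemap.DEFAULT_MAPPING`; any alternative landmark
ordering needs only a new mapping). Mouth width/height use the inner lip
contour by default (configurable through the mapping).

**Texture (31 patches).** 32×32 Regions Around Points (RAPs) are centered
on 31 configured landmarks (full brows, eye corners and mid lids, nasal
root/base, mouth outline — `facemap.DEFAULT_RAP_INDICES`), chosen to cover
the regions where pain wrinkles appear. Patches follow the moving landmark
frame by frame; out-of-bounds pixels replicate the image edge. Per frame,
each RAP contributes the mean 3×3-Sobel gradient magnitude over its crop
(gradients are computed on the full image with reflective boundaries, then
cropped), giving 31 texture values per frame.

## Temporal descriptors

Each frame-level signal `x` is smoothed to `s` by a **first-order
Butterworth low-pass at 1 Hz**, applied forward-backward (zero phase) so
peak-time descriptors inherit no phase lag; the effective amplitude
response is the squared first-order magnitude of the digitally designed
(bilinear, prewarped) filter. `v` and `a` are first/second derivatives by
central finite differences scaled by the sampling rate, one-sided at the
ends. The sampling rate must exceed 2 Hz (cutoff below Nyquist); it is
carried in the landmark file header and defaults to 30 Hz in the generator.

Sixteen descriptors are read off each of `s`, `v`, `a`:
state (max, min, mean, median); variability (range, population SD, IQR,
inter-decile range, MAD); peak time (first maximum index / fs, seconds);
durations strictly above the mean and above (mean+min)/2 (seconds);
counts of maximal runs above those two thresholds; AREA (rectangle-rule
area above the minimum, bin width 1/fs) and AREA/(max−min), defined as 0
for a flat signal. Quantiles use linear interpolation. These conventions
(strict `>`, first-occurrence argmax, rectangle rule, flat-signal quotient)
are fixed here and locked by brute-force oracle tests.

48 descriptors per signal concatenate, in frozen (signal, component,
descriptor) order, into the streams `DG_DisFace` (528 = 48×11),
`DG_DisPose` (384 = 48×8) and `DA_Gradient` (1488 = 48×31).

## LBP-TOP (5487 = 177 × 31)

For each RAP's volume (t, y, x), 8-neighbor local binary patterns with
radius 1 on the integer 8-connected ring (no interpolation; tie rule
neighbor ≥ center → 1) are coded on the three orthogonal plane families:
XY frames, XT slices (one per row) and YT slices (one per column). Every
pixel interior to its own plane is coded. Codes map to the 59-bin
uniform-2 histogram (58 patterns with ≤2 circular transitions, in
ascending code order, plus one catch-all bin). The three histograms are
L1-normalized per plane (flag-controlled; normalization is not dictated by
the printed dimensions) and concatenated XY‖XT‖YT → 177 per patch, 5487
per video. The descriptor is invariant to adding a constant gray level.

## SLPP embedding

Per stream, features are standardized (per-dimension zero mean, unit
variance) and pre-projected by a PCA retaining 98% of the variance — this
keeps the constraint matrix nonsingular when dimensionality exceeds the
sample count, as it does for every stream. On the pre-projected data `Z`,
the supervised adjacency is
`W_ij = exp(-||z_i − z_j||² / t)` iff `i` and `j` share a class label and
either is among the other's k nearest neighbors (k = 5, symmetrized by
max), else 0. With `D = diag(W·1)` and `L = D − W`, projection directions
solve the generalized eigenproblem `ZᵀLZ a = λ ZᵀDZ a` (tiny ridge
`1e-10·(tr B/r + 1)` on B for isolated samples); the `d_out` smallest-
eigenvalue directions are kept, `d_out = min(30, rank)` by default, where
an explicit `d_out` above the achievable rank is an error. The heat-kernel
width `t` defaults to the mean squared pairwise distance of the training
data. All four knobs (`k`, `t`, `d_out`, PCA variance) are configuration
keys; none is constrained by the printed feature dimensions.

## Classification, fusion, evaluation

Each stream trains its own RBF SVM (C = 1) on the embedded features. The
embedded coordinates are re-standardized before the kernel so the default
width `gamma = 1/d_out` operates on a unit-variance scale regardless of the
eigenvector normalization. The signed decision score carries the vote
(sign; positive = pain) and the confidence (magnitude).

Fusion is majority voting: the label with more than half the votes wins;
on a tie (possible only with an even voter count) the single most
confident voter decides. The fused ROC score is the confidence-weighted
vote sum (+confidence for a pain vote, −confidence otherwise) — an
artifact convention, monotone in the vote margin. AUC is the trapezoidal
area (equivalently the Mann–Whitney probability with half-credit ties).

LOSO evaluation holds out all epochs of one subject per fold; accuracy is
pooled over instances (not averaged over folds). Folds whose training
labels collapse to a single class are skipped with a warning and reported,
never silently dropped. Subgroup models filter by gender, race, or
gestational age with the clinical cut preterm < 37 weeks, full-term 37–42.

**Hemiface models** keep the features of one anatomical side plus the
midline features — `d_nm`, `d_mw`, `d_mh` and the midline patches — in both
hemifaces, so a profile model retains the mouth/nose evidence still
visible from the side; left ∪ right covers every lateral feature once and
midline features twice.

## Ground truth

NIPS rates facial expression, breathing, arms, legs and arousal as 0/1 and
cry as 0/1/2; the total (0–7) labels an epoch pain at ≥ 3, with severity
none (0–2) / moderate (3–4) / severe (> 4). Procedure videos are cut into
seven half-open epochs: up to 300 s of baseline (T0), the procedure (T1,
duration from the annotation), and five 60-s windows (T2–T6), truncated
and flagged at the video end; epochs map to frames by
`[floor(start·fs), floor(end·fs))`.

## Synthetic cohorts

The generator animates a fixed, bilaterally symmetric neutral 68-point
template on a 256×256 canvas and renders schematic grayscale frames
(face ellipse, brow bands, eye/mouth polygons, nose lines) so that every
feature stream has signal to work with. Pain epochs superimpose, scaled by
a smooth within-epoch activation bump: brow drop (default 6 px), eyelid
closure (5 px), mouth opening (10 px), a 1-Hz sinusoidal lateral boundary
shift (4 px), and oriented 4-px-wavelength gratings in the glabellar and
nasolabial patch regions (30 gray levels). All landmarks receive 1 px
Gaussian jitter and frames 2 gray levels of pixel noise. The effect sizes
were chosen once to represent clearly expressed pain relative to plausible
landmark-tracking noise; they are the package's reference condition, and
every magnitude is configurable. NIPS indicators are drawn consistently
(pain totals ≥ 3, no-pain ≤ 2); gestational ages are drawn from a normal
(36.4, SD 2.7) clipped to 30.4–40.6 weeks, genders alternate, races follow
configurable proportions. A spec plus seed reproduces the cohort
bit-exactly.

What the generator does **not** emulate: photorealistic infant appearance,
landmark-detector failure modes (occlusion, gross mistracking), lighting
changes, out-of-plane rotation, correlated inter-epoch subject identity in
texture, or label noise in NIPS ratings. Passing end-to-end checks on
these cohorts therefore demonstrates that the pipeline recovers the
constructed effects through every stage — not that it reaches any
particular accuracy on clinical recordings.

## Problem sizes of the built-in checks

The end-to-end recovery check uses 12 subjects × 4 epochs × 45 frames with
the default effect sizes (three-stream fusion with LBP-TOP, LOSO accuracy
≥ 95%). Null-behavior (mean LOSO AUC within 0.5 ± 0.1 over 20 seeds with
all effects zero) and effect-size monotonicity (10 seeds × brow-drop
amplitudes 0/2/5/10 px) run on landmark-only cohorts of 6 subjects × 4
epochs × 30 frames with the deformation stream, which isolates the
geometry path and keeps the checks cheap. The hemiface comparison uses 8
subjects × 4 epochs × 30 frames with head shake disabled (bilateral
symmetry) and the gradient-based three-stream fusion; left, right and
whole-face accuracies must agree within 5 percentage points.

## Known limitations

* The SLPP graph is built on PCA-projected distances; with heavy-tailed
  features the heat-kernel width heuristic can over-smooth the graph.
* The 31-RAP placement and the landmark-group anchors are sensible
  defaults, not fitted to data; both are configuration, not code.
* `libsvm` convergence tolerance (1e-3) limits exact symmetry properties
  of decision scores to ~1e-3.
* The generator's pain effects are additive and temporally smooth; abrupt
  or partial expressions are not modeled.
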