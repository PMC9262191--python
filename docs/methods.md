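# Methods

This note documents the models, conventions and numerical choices behind
`mitotrack`, in the spirit of a software methods section: what each stage
computes, which parameters matter, and what the synthetic benchmark does
and does not establish.

## Conventions

Coordinates are 0-based `(row, col) = (y, x)`; frame indices are 0-based;
all frame windows are half-open `[start, end)`.  Orientation angles are
axial (nuclei have no head or tail): degrees from the +x (column) axis,
wrapped into `[-90, 90)`; angular differences always take the short way
around the 180° wrap, so 88° → −88° is a 4° step.  Images are unsigned
16-bit; 8-bit inputs are upcast without rescaling.  Mitotic states are
0 invalid, 1 interphase, 2 prophase through early anaphase, 3 late
anaphase/telophase; the IP anchor is the first state-2 frame, the MA
anchor (anaphase onset) the first state-3 frame, and sister cells always
share identical state sequences.

## Detection

The scale-normalized negated LoG response `-σ²·(G_σ * I)''` is evaluated
on a grid of scales (default six scales spanning ±40% around
`d/(2√2·p)`, with `d` = 13 µm expected nucleus diameter and `p` the pixel
size — 7.1 px at 0.65 µm/px).  The image mean is subtracted first because
the truncated discrete LoG kernel does not sum exactly to zero; this makes
detection exactly invariant to constant intensity offsets.  Local maxima
of the (scale, y, x) volume above `threshold_rel` (default 0.1) times the
per-frame maximum response are accepted strongest-first; a weaker maximum
within `max(σ_kept, σ_new)·√2` of an accepted one is merged into it.
Centroids are refined by the positive-response centroid of the 3×3
neighbourhood.  The relative threshold makes the detector robust to global
intensity scaling across microscopes.

## Tracking

Linking runs backward from the last frame.  Per step, the union of
current-frame and next-frame centroids is clustered with Ward's linkage
and cut at a distance cutoff — either user-supplied or the heuristic
`0.5 × mean over objects of the mean distance to their min(8, n−1)
nearest neighbours`.  Within each cluster every next-frame object links to
its nearest current-frame object.  A current-frame object with exactly two
successors of different track ids marks a division at the successors'
frame (the first frame at which two daughters exist, i.e. early anaphase);
more than two successors is rejected and logged, since only binary
division is modelled.  There is no gap closing: a missed detection
terminates a track.  Trajectory extraction keeps divisions whose parent is
tracked for `n_before` (default 30) frames before and both daughters for
`n_after` (default 60) frames after the division, trimming to exactly that
window; sisters share the identical pre-division segment.

## Segmentation

For each tracked centroid a square patch (default 96 px at 0.65 µm/px,
scaled inversely with pixel size — a physically constant field of view,
and rounded even) is cropped, padded with the frame minimum at borders.
The classical pipeline: 5×5 median filter; 256-bin Otsu threshold over the
patch min–max range, averaged with the filtered minimum of the central
square covering half the patch side (this protects a dim central cell next
to a brighter neighbour from being thresholded away); seeded watershed on
the inverted Euclidean distance transform of the binarization.  Seed 1 is
the patch centre; seed 2 represents background *and neighbouring cells*:
the border ring plus distance-map maxima farther than `max(6, S/10)` px
from the centre.  Without neighbour seeds, the basin of a touching
neighbour floods from the centre seed and the mask absorbs the sister
cell.  The centre-seed region is intersected with the binarization,
reduced to the 4-connected component at (or within 5 px of) the centre,
and holes are filled, since chromatin texture creates interior minima and
area features assume solid regions.  Because the Otsu bins and the centre
minimum both scale with the data, masks are invariant under positive
global intensity scaling.

External instance segmentations are consumed as 16-bit label TIFFs
(0 = background).  Per detection the label at (or nearest within 5 px of)
the patch centre is kept — neighbouring instances are discarded — and
missing labels fall back to the classical pipeline with a flag.

## Features

Morphology comes from the mask's second central moments with the standard
+1/12 pixel-area correction (the ellipse with equal moments); circularity
is `4π·area/perimeter²` with the perimeter measured as the
marching-squares boundary contour of the lightly smoothed (σ = 0.8 px)
mask — a raw pixel contour overestimates a disk's perimeter by ~9%,
whereas this estimator keeps disk circularity within 0.98–1.08 for radii
3–18 px.

Texture: the patch is quantized to 64 uniform levels over its own min–max
range (making texture invariant to linear intensity scaling across
platforms); co-occurrence matrices count only pixel pairs with **both**
pixels inside the mask, removing background→foreground transitions, for
the offsets (0,1), (1,0), (1,1), (−1,1).  Thirteen Haralick statistics are
computed per offset with base-2 logarithms (entropies in bits) and
averaged across offsets.  Two ambiguities in the original definitions are
resolved as follows: the "sum of squares: variance" statistic centres on
the row-marginal mean µ_x, and the sum variance centres on the sum average
(not the sum entropy, a known erratum).  The numerically unstable 14th
statistic (maximal correlation coefficient) is omitted.  A degenerate
matrix with a single nonzero cell has undefined correlation, which is
reported as NaN while the other statistics are kept.

Second-channel (spindle) statistics are evaluated on the chromatin mask
dilated or eroded with a disk (default radius 15 px) or on their
difference (the toroidal band), plus the displacement of the intensity
maximum from the chromatin centroid — a proxy for astral signal moving
toward the poles.  Sister distance is the per-frame centroid distance in
µm, defined as 0 before the division (a single chromatin mass).  Plate
rotation is summarized by the summed absolute per-step orientation change
over [IP, MA) and by the mean absolute axial difference to the
sister-separation axis at MA; both formulas are declared conventions, as
no canonical definition exists.

## Synchronization

The classical pathway z-scores (area, circularity, mean intensity,
intensity std.) over the pre-division window and finds the IP anchor as
the contiguous two-cluster split minimizing the total within-cluster sum
of squares — computed by exhaustive search over all splits, which *is* the
constrained two-cluster optimum; ties break to the earliest split.  If the
best split beats a constant model by less than a factor 1.2 in cost the
trajectory is flagged low-confidence (a track that never condenses), but
not auto-rejected.  The MA anchor is the first post-division frame whose
sister centroid distance exceeds a threshold (default 10 px at
0.65 µm/px, scaled with pixel size; a mandatory, documented setting),
falling back to the division frame itself.

The HMM pathway accepts any per-frame state-probability table (rows
summing to 1 over states 0–3).  Transitions allow only self-loops and
1→2, 2→3 (self 0.9, advance 0.1); the start distribution permits states 0
and 1.  Viterbi decoding runs in log space with ties preferring the lower
state; an all-0 winning path, or one that never reaches states 2 and 3,
marks the trajectory invalid.  A built-in fixed-coefficient softmax model
on the z-scored classical features plus normalized sister separation
serves as the default probability source, standing in for any external
per-frame classifier.

Manual annotations come from CSV (`cell_id, last_interphase_frame,
early_anaphase_frame, reject`): IP = last interphase frame + 1,
MA = early anaphase frame + 1, all intermediate frames classified
accordingly, the annotation copied bit-identically to the sibling;
`reject` zeroes the whole pair.

## Derived features

Series can be smoothed (moving average with edge windows truncated to the
available samples, LOWESS, or Savitzky–Golay), normalized by the
interphase mean or the value at the first late-anaphase frame (whose
normalized value is exactly 1), and summarized by OLS slopes over a small
window after an anchor (default 5 frames; per frame and per minute).  The
recovery feature reports `100 − mean_f min(100, |v_f(t) − µ_f|/µ_f·100)`
over the selected features (default: area, minor axis length, mean
intensity, intensity std.), so 100% means full recovery and deviations
clip at 100% to keep the scale interpretable under intensity overshoots
(clipping is toggleable).  Zero interphase means drop the feature from the
average with a warning.

## Selection, statistics and reports

Selections intersect metadata equality predicates with inclusive ranges on
per-cell single features (e.g. the per-feature interphase means attached
by the derivation step).  Temporal displays use a three-segment aligned
axis: interphase block ending at IP, the variable-length [IP, MA) block
stretched uniformly onto a fixed number of positions, and the post-MA
block; IP and MA map to the same axis position for every cell and the
mapping is monotone.  The fold-change report compares each feature's
interphase mean with the mean over the first two state-2 and first two
state-3 frames (window configurable), ranks by the larger |log fold|, and
renders a static HTML page with PNG mean±sd plots.  Group comparisons use
scipy's two-sample t, one-way ANOVA, Wilcoxon rank-sum and Kruskal–Wallis
tests; the two-way treatment×time ANOVA resamples each cell's [IP, MA)
block onto 10 time bins (the original formulation leaves the handling of
variable-length blocks open) and fits `value ~ C(treatment)*C(time)` with
a type-II table.  Raw p-values are exported alongside Benjamini–Hochberg
adjusted ones; error bands default to one standard deviation, with SEM as
an option.

## Synthetic movies

Each nucleus is a super-Gaussian elliptical profile
`A·exp(−u⁴)` (u the normalized elliptical radius), so thresholding and
watershed face smooth, non-binary edges.  Defaults describe a HeLa-like
field at 0.65 µm/px and 3 min/frame: 600×600 px, 120 frames, 20 nuclei of
~11 px semi-major axis (axis ratio 0.8) with ±5% size jitter, amplitude
100 over background 10, Gaussian noise σ = 2, random walks of
σ = 0.5 px/frame, and five divisions placed so the default 30/60 window
fits.  Mitosis per dividing cell: condensation is a step at the IP frame
(10 frames before division) to a circular blob with radii scaled by 0.6
and amplitude gain 1.4; after 4 frames the blob becomes the metaphase
plate (an elongated bar perpendicular to the division axis, oscillating
±15° with period 8 frames); at the division frame two daughters appear
12 px apart along the random division axis and separate at 1.5 px/frame
until 26 px; over 20 frames they ease linearly back to the parent's
interphase geometry and intensity.  Ground truth records per-frame
centroids, instance masks and states plus per-cell division/IP/MA frames;
overlapping masks are rejected as an invalid configuration.  The second
channel renders two pole foci and a bridge along the division axis during
mitosis and a faint diffuse signal otherwise.

Because the profile shape is identical relative to the mask radius, the
in-mask mean intensity scales with the amplitude: the measured
condensation intensity fold is slightly below the configured gain (1.35
vs 1.4) due to the constant background, and the area fold equals the
shrink factor squared up to rasterization.

What the generator does **not** emulate: photorealistic texture, 3D,
cell death or fusion, stage drift, illumination gradients, segmentation-
confounding clutter, and cell crowding beyond the configured spacing.
Passing the end-to-end benchmark therefore demonstrates the internal
consistency and accuracy of the pipeline under controlled dynamics — not
performance on real microscopy, which varies with SNR, density and
morphology.

## Problem sizes and determinism

The test suite exercises a 5-cell/100-frame movie for module-level checks
and the full 20-cell/5-division/120-frame conditions for the end-to-end
benchmark; these sizes keep a complete run in the low minutes on one CPU
while containing every phenomenon the pipeline measures.  All randomness
flows through seeded `numpy` generators: a fixed seed reproduces movies
bit-identically, and tracking, segmentation and synchronization are fully
deterministic (Ward-linkage ties resolved by scipy's fixed node ordering,
argmax ties by lowest index, TC3 ties by earliest split).
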