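# Methods

## Input contract

The tool consumes a reconstructed T2-weighted fetal brain volume and a
co-registered integer label volume, both NIfTI, nominally 0.5 mm isotropic.
Labels follow the FeTA seven-tissue convention (0 background, 1 external
CSF, 2 grey matter, 3 white matter, 4 ventricles, 5 cerebellum, 6 deep grey
matter, 7 brainstem); other schemes can be supplied as a JSON side-file
mapping integers to tissue names. Brain extraction, super-resolution
reconstruction and tissue segmentation are upstream producers of these
inputs and are out of scope here — the pipeline starts where a label volume
exists.

Anatomical axes are taken from the NIfTI affine (nibabel axis codes); when
the affine is unusable the volume is assumed RAS with a warning. Laterality
and the identity of the "axial" axis are derived from this code, never from
array-axis position. Voxel indexing is 0-based; the reported slice index is
the 0-based array index along the superior–inferior axis.

## Reference-slice selection

The per-slice deep-grey-matter area (DGM voxel count × in-plane pixel area)
is computed along the superior–inferior axis and the argmax taken, with ties
broken to the smallest (most inferior) index. No smoothing is applied — the
profile of a thalamic DGM mass is unimodal in practice and the plain
maximum keeps the rule transparent. The selection does not require the
chosen slice to contain ventricle voxels; a warning is logged if it does
not, and the component stage then fails with a stage-named error.

## Component extraction and laterality

Connected components of the ventricle label on the reference slice use
8-connectivity; components under 4 pixels are discarded as speckle (logged).
The two largest components are the lateral ventricles. The one whose
centroid lies on the subject-left side of the image midline (per the
orientation code) is the left ventricle; if both large components fall on
the same side, a warning is emitted and assignment proceeds by relative
position. A third component whose centroid lies between the two along the
left–right axis is recorded as the cavum septum pellucidum and excluded
from measurement.

## Binarization

Within one component, the threshold m is the mean intensity over the
component's pixels, and pixels with intensity ≥ m are kept (the comparison
is ≥, so a perfectly uniform component keeps itself). Of the kept set only
the largest 8-connected piece is retained; if nothing survives, the input
component is used unchanged and no plexus is reported. The removed
remainder is retained for the `plexus_margin` mode; a plexus is "detected"
when some removed 8-connected cluster reaches the 4-pixel floor. On
T2-like contrast the choroid plexus sits far below the CSF mean, so this
single global threshold removes it together with dark segmentation fringe.
The kept-pixel set is idempotent under the stored threshold: every retained
pixel is ≥ m by construction.

When the binarized mask splits into several pieces, measuring on the
largest piece (rather than the unrefined segment) is this package's
documented choice.

## Width measurement

The minimum-area enclosing rectangle of the refined mask's pixel centers is
computed exactly by enumerating convex-hull edge directions (the optimal
rectangle is flush with a hull edge), not by angular search. Side lengths
are converted to mm and augmented by one pixel pitch to account for pixel
extent; collinear masks degenerate to a one-pitch short side. A single
scalar width requires isotropic in-plane spacing (1% tolerance);
anisotropy is an error rather than a silently wrong number.

- **minrect** (default): the width is the rectangle's short side — the
  diameter perpendicular to the ventricle's long axis. Deterministic and
  anchor-free.
- **plexus_margin**: the ventricle is rotated so the rectangle's long side
  is horizontal; the removed cluster nearest the posterior end is located,
  and at the horizontal station of that cluster's margin closest to the
  component centroid the width is the vertical extent of the refined mask
  (one pixel pitch added; widened by one pitch if the exact column is
  empty). This emulates placing the caliper at the posterior margin of the
  glomus, the clinical landmark. Without a removed cluster it falls back to
  `minrect`.
- **auto**: `plexus_margin` when a plexus was detected, else `minrect`.

The clinical literature's "line moved toward the choroid plexus" has no
published stopping rule; both modes are labeled in the output and neither
claims to replicate unpublished code. The reported width never exceeds the
rectangle's long side.

## Classification

Ventriculomegaly iff either side exceeds 10.0 mm strictly ("wider than
10 mm"); exactly 10.0 mm is normal. Grades: normal ≤ 10, mild (10, 13),
moderate [13, 15], severe > 15 — the conventional integer ranges leave
(12, 13) unassigned, folded into mild here; edges are configurable. The
asymmetry flag (|left − right| > 2.4 mm) applies only to cases without
dilatation, per the clinical phrasing. All thresholds live in `RunConfig`.

## Agreement statistics

Mean absolute differences are reported per side and pooled (right and left
concatenated, 44 ventricles for 22 cases); R² is the squared Pearson
correlation (this definition reproduces the published right-ventricle value
to nine decimals, confirming the interpretation); the t-test is paired,
two-sided, Student's t with df = n−1 over the pooled ventricles; the error-
threshold count uses strict `<` (default ε = 1.7 mm); summary SDs use the
sample (n−1) denominator. Display rounding is decimal half-up to 2 places;
all internal comparisons use full precision.

Known print-side inconsistencies in the benchmark source, verified by test:
the printed paired-t p-values (0.0043 / 0.9827 / 0.2378) are not
reproducible from the printed per-case widths (recomputation gives
0.0527 / 0.9479 / 0.2733); the abnormal-case AI column means print as
11.22 / 10.79 but recompute to 12.75 / 12.25 from their own rows; one
normal-case SD cell prints 1.29 where the data give 1.2991 (→ 1.30); the
abstract quotes 0.82 mm for the neuroradiologist-vs-AI pooled difference
where the table-consistent value is 0.84 mm; and the left-ventricle R²
0.9354 appears in print as 0.93, i.e. truncated rather than rounded. The
bundled fixture keeps the per-case values and recomputes all summaries.
The strict-`<` threshold count for neuroradiologist-vs-AI is 40/44, which
includes one knife-edge pair (8.7 − 7.0 evaluates just below 1.7 in binary
floating point).

## Synthetic phantom

The phantom emulates exactly the features the pipeline depends on: nested
ellipsoidal CSF/GM/WM shells; two ventricle ellipsoids whose axial
cross-section at the chosen reference slice has a prescribed minor diameter
(the atrial width), with the major axis rotated in-plane and
mirror-symmetric placement about the midline; a DGM blob whose axial area
peaks exactly at that slice; small cerebellum and brainstem blobs; an
optional midline CSP component carrying the ventricle label; and an
optional choroid-plexus region in each ventricle's posterior third whose
intensity (40) is far below half the within-ventricle mean (≈ 200), so the
mean-threshold binarization provably removes it. Intensity noise is
additive Gaussian (default SD 4, clipped at zero), seeded and reproducible.

Ellipse centers are snapped to the voxel grid so that at rotation 0° the
realized minor diameter is exactly round(w / spacing) voxels; the recorded
ground-truth width is measured independently of the pipeline by projecting
the slice cross-section's voxel centers onto the known minor-axis direction
(span + one pitch). Default geometry: 144×144×80 voxels at 0.5 mm
(a 72 mm brain, mid-gestation scale), ventricle length 24 mm, height
12 mm, reference slice 40.

What the phantom does *not* model: cortical folding, partial-volume
effects, bias fields, motion artifacts, segmentation errors beyond
intensity fringe, or the asymmetric frontal-horn anatomy of real atria.
Passing the phantom sweep therefore demonstrates geometric correctness of
the measurement chain, not clinical accuracy on real MR data — the
published clinical accuracy figures (95% case accuracy, 21/24 abnormal
ventricles within 1.7 mm) depend on institutional data and a trained
segmentation network and are not desk-reproducible here.

## Verification problem sizes

The width-recovery sweep uses 16 phantoms (widths 6/9/12/16 mm × rotations
0/15/30/60°, default grid) with acceptance bounds mean ≤ 0.75 mm and
max ≤ 1.5 mm on absolute width error (measured values come in around
0.23 / 0.44 mm). The rectangle oracle compares the exact calipers area
against a 0.1°-stepped brute-force rotation minimum on 200 uniform point
sets of 8–30 points within 0.5%; point sets of fewer than ~5 points can
produce needle-thin hulls for which the coarse rotation grid itself—not the
calipers—is a poor reference, so the oracle sets are kept at ≥ 8 points
where the grid comparison is well-posed. Most unit tests run the phantom
on a compact 96×96×48 grid for speed; geometry-critical tests (steep
rotations, the acceptance sweep) use larger grids.
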