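# Methods

## Problem and pipeline

`petindex` quantifies skeletal tumor burden in bone-seeking-tracer PET/CT.
A whole-body scan is represented as co-registered volumes on one grid: CT in
Hounsfield units, PET in SUV, and an integer label mask assigning each voxel
to one of eleven anatomical regions (background, bones, joints, kidneys,
lungs, brain, skull, spleen, heart, aorta, liver) — the regions where either
malignant or physiological high uptake is common. Two segmentation models
mark voxels suspicious for bone metastasis:

* a **fixed SUV threshold** (default 15, inclusive) followed by removal of
  connected components below 0.1 ml;
* a **label-mask-conditioned 3D U-Net** that classifies each voxel from CT,
  PET and the label mask, followed by the volume filter, a watershed-based
  joint-uptake suppression, and a second volume filter.

The **PET index** of a segmentation is

    PET index [%] = 100 × (volume of all marked voxels) / (skeletal volume),

where skeletal volume counts bone, skull and joint voxels of the label mask.
Marked voxels outside the skeleton still count toward the lesion volume
(readers legitimately mark cortical-edge voxels); the index is therefore not
capped by construction, though in practice it lives in [0, 100].

## Volume model and resampling

Grids are stored axis-ordered (slice, row, column) with spacing in the same
order; the clinical working grid is 3.0 × 1.37 × 1.37 mm, slice spacing
first. Resampling preserves the physical extent with output shape
`round(extent / target_spacing)` per axis; sample points are clamped to the
source domain at the edges (half-voxel edge handling). Scalar channels are
interpolated trilinearly; label and binary channels are always
nearest-neighbour so fractional labels cannot appear. Volumes are exchanged
as NIfTI-1 files with a JSON manifest naming the channels of a case;
co-registration is verified on load (shape exact, spacing within 1e-3 mm,
origin within 1e-2 mm). DICOM ingestion is out of scope.

## Postprocessing

**Connected components** use 26-connectivity by default (6/18 available);
blob-like lesions are conventionally 26-connected. **Small-component
filtering** removes components with volume < 0.1 ml (strictly below: a
0.099 ml component is removed, 0.100 ml survives).

**Joint suppression**: each segmented voxel is attributed to a regional
maximum of the SUV image by a watershed transform on the negated SUV,
seeded at the regional maxima of a one-voxel-dilated envelope of the
segmentation (locality bounds cost and matches the intent of attributing
high-uptake regions to nearby peaks). Voxels whose basin maximum lies in
the joint mask are cleared. Plateau maxima collapse to a single marker
whose representative is the lexicographically smallest index. The joint
mask is the union of explicitly labeled joint voxels and interfaces where
dilations (default 3 mm) of two distinct skeletal labels overlap; with the
compact region vocabulary the distinct labels are "bones" and "skull", and
an optional per-bone instance grid resolves finer articulations. In the
learned-model path the order is: volume filter, joint removal, second
volume filter — basin removal can fragment a component below 0.1 ml. The
baseline threshold path applies only the volume filter, no joint removal.

Both filters are idempotent and never add voxels; the watershed basin
attribution is cross-checked in the tests against an independent
steepest-ascent hill-climbing oracle on fields built from well-separated
Gaussian bumps, where the basin decomposition is unambiguous.

## The lesion network

A valid-convolution 3D U-Net (blocks of 3×3×3 convolution + ReLU, 2× max
pooling, nearest-neighbour upsampling, center-cropped skip concatenation,
1×1×1 head, softmax over two classes), implemented in NumPy with manual
backpropagation and Adam. Because all convolutions are valid, the predicted
window is strictly inside the input patch:

| configuration | input | output | depth | convs/block | base filters |
|---|---|---|---|---|---|
| clinical | 100³ | 12³ | 3 | 2 | 16 |
| desk / tests | 36³ | 12³ | 1 | 3 | 8 |

Input channels: CT clipped to [−1000, 1500] HU and scaled to [−1, 1]; SUV
divided by 15 and clipped at 4 (fixed, not per-case, so SUV keeps its
meaning across scans); one binary occupancy channel per region (one-hot
rather than a single integer channel, avoiding false ordinality). Border
patches are padded with air CT, zero SUV and background labels.

**Sampling.** Patch centers are drawn evenly from the two classes
(Bernoulli 1/2 per patch); within a class, voxel weight is
`1 + high_suv_boost·[SUV > 10] + hard_example_boost·[misclassified]`, both
boosts defaulting to 5. Hard-example maps can be refreshed once at
mid-training from the current model (off by default). Requesting
lesion-class patches from a lesion-free case is a sampling error; the
trainer redirects those draws to a lesion-bearing case.

**Inference** tiles the volume with stride equal to the output window, so
every voxel is predicted exactly once (asserted in tests as a coverage
map ≡ 1); context is padded as above, the probability map is resampled back
to the native grid, binarised at 0.5, and postprocessed as described.

Training sizes used in tests and in the acceptance run: eight 48³ phantoms,
the desk configuration, 10 epochs of 128 patches in batches of 4,
learning rate 2e-3 — small batches and a generous per-epoch patch count
keep the number of Adam steps (320) high enough for reliable convergence
within the short epoch budget. This recovers held-out Dice well above 0.5 on
phantoms and a clean zero PET index on lesion-free scans; those runs
characterise the implementation, not clinical performance.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes, at
desk scale (default 48³ voxels at 3.0 × 1.37 × 1.37 mm): an elliptical
soft-tissue body (≈40 HU, SUV 1) in air (−1000 HU); a spine-like bone
cylinder and a skull sphere (700 HU, diffuse SUV 5) with a brain inside;
kidneys, lungs, heart, liver, spleen and aorta with per-organ SUV defaults
(kidneys 8, lungs 0.4, brain 0.3, others 1.5–2.5); five degenerative-style
joint blobs riding on the spine surface with SUV drawn from 14–25, so joint
confounders genuinely cross the threshold and give the watershed path real
work. Lesions are spheres quantized to the grid, centers confined to bone
with the whole sphere inside bone, pairwise disjoint with a two-voxel gap
(so component counts are exact); radii default to 4–6 mm and SUV to 10–30 —
a span deliberately straddling 15 so a fixed threshold misses part of them.
Gaussian SUV noise (σ = 0.5) is added and floored at 0; optional Gaussian
smoothing approximates scanner PSF but is off by default.

Simulated readers perturb the ground truth: per-lesion Bernoulli misses,
boundary dilation/erosion in millimetres, and Poisson-distributed spurious
marks (≥ 0.1 ml spheres placed in bone away from true lesions). Everything
is deterministic given the spec/profile seeds; cohort case *i* uses
`seed + i`.

What the phantoms do **not** model: realistic skeletal anatomy and uptake
texture, partial-volume effects, reconstruction artefacts, PET/CT
misalignment, confluent disease, and reader behaviour correlated with image
ambiguity. Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover known structure under the stated noise
model — not that the trained desk-scale network would perform on clinical
scans.

## Evaluation framework

Each reader is alternately held as reference and every other participant
(reader or model) is compared against it; pairwise results are averaged
over the reference choices. Patient level: TP when candidate and reference
both have PET index > 0, FN when only the reference does, FP when only the
candidate does; both-zero scans contribute to no count, so no true negative
(and no specificity) exists. Lesion level: a reference component with any
overlap from the candidate is TP (one candidate blob may validate several
reference lesions), zero overlap is FN; a candidate component with zero
overlap with the reference marking is FP. Sensitivity = TP/(TP+FN), PPV =
TP/(TP+FP); undefined ratios are reported as absent, never silently zero.
The averaged rows report both the mean of pairwise sensitivities and the
sensitivity of pooled counts — these differ, and both are labeled.

Spearman correlation uses average ranks under ties and is banded on |r|:
[0.8, 1] very strong, [0.6, 0.8) moderately strong, [0.3, 0.6) fair,
[0, 0.3) poor; the half-open bands resolve the boundary values the verbal
convention leaves ambiguous. Bland–Altman agreement is computed on
log10(x+1)-transformed indices (the +1 keeps zero-burden scans in the
domain and maps index 0 to 0); limits of agreement are mean ± 1.96 × sample
SD (n−1), back-transformed as 10^LoA − 1. Reports are emitted as JSON plus
per-pair CSV, with optional matrix/Bland–Altman figures.

Display rounding follows the reporting convention used throughout:
integer percentages for lesion-level sensitivity/PPV, one decimal for
per-patient counts.

## Numerical and degenerate-input choices

* Threshold comparison is inclusive (SUV ≥ threshold), surfaced in config.
* Resampling to the identical spacing is an exact identity; constant fields
  stay constant; trilinear interpolation is exact on affine ramps away from
  the clamped border.
* A label mask without skeletal voxels makes the PET index undefined — an
  error, not a zero.
* Correlation of a constant series is undefined — an error, not 0 or 1.
* Watershed with an empty joint mask or an empty segmentation is the
  identity.
* All randomness flows through explicit integer seeds; identical seeds give
  bit-identical phantoms, reader masks, sampled patches and trained weights.

## Known limitations

* The anatomy-segmentation stage is replaced by phantom ground-truth label
  masks behind the same interface; real scans would need an external organ
  segmentation to produce the label mask and skeletal volume.
* The NumPy network trains on one CPU at desk scale; the clinical 100³
  configuration is implemented and shape-verified but not trained here.
* Lesion-free training cohorts cannot train the lesion class; the trainer
  requires at least one lesion-bearing case.
* Watershed basin boundaries on plateaus follow the marker convention
  described above; other tie-breaks are equally defensible.
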