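# Methods

This note documents the models and procedures the toolkit implements, the
choices made where the design was open, and what the synthetic experiments
do and do not demonstrate.

## The problem

Multi-hospital mammography collections are heterogeneous in ways that are
invisible to a radiologist but fatal to a shared model: scanners store pixels
over different raw ranges and under opposite photometric conventions
(MONOCHROME1 stores low values for bright display), films carry printed
laterality/view labels and surgical clips, and a minority of studies show
implants or truncated scans. In federated training — where each hospital
trains locally and a server only averages model parameters — this
heterogeneity is amplified: a hospital whose images look systematically
different drags the merged model away from its own test distribution, while
no one can inspect the data to see why. The toolkit implements a
harmonization-first answer: normalize everything the DICOM metadata can
explain, segment and keep only the breast region, share normalization
statistics, and only then federate.

## Metadata-driven harmonization

For every image the chain applies, in order:

1. **Rescale**: `out = slope * stored + intercept` from the Rescale
   Slope/Intercept attributes (slope 0 is rejected as degenerate).
2. **Inversion**: stored values are inverted (`max(pixels) − pixels`) iff the
   Pixel Intensity Relationship Sign is +1, the Photometric Interpretation is
   MONOCHROME1, or the Presentation LUT Shape is INVERSE. The image maximum —
   not the theoretical bit-depth maximum — is used deliberately; it makes
   inversion an involution on images whose minimum is 0 and avoids trusting
   a Bits Stored attribute the chain does not otherwise need.
3. **Windowing**: intensities are clipped to the [0.5, 99.5] percentile range
   (configurable). The bounds are order statistics rather than interpolated
   percentiles so that windowing an already-windowed image is exactly a
   no-op, which keeps the whole chain idempotent. Windowing runs after
   inversion so the percentiles are taken on the display-oriented image.
4. **Laterality alignment**: right-breast images are column-flipped so the
   breast always touches the left border. Missing laterality is an error,
   never a default — silent mis-orientation would bias every downstream
   model. Other attributes default to their non-inverting values with a
   warning.
5. **Spacing-aware resize**: anisotropic images are first resampled onto an
   isotropic grid at the coarser of the two spacings (preserving physical
   aspect ratio without upsampling), then scaled to the target size —
   512×512 for segmentation input, 256×256 for classification input after
   cleaning. Images interpolate bilinearly; masks use nearest-neighbour so
   they stay binary.

## Breast-area detection (BAD)

Supervision is bootstrapped, not annotated:

- **K-means candidate masks** (k = 2): pixel intensities are clustered;
  everything brighter than the darkest cluster is foreground; the largest
  connected component, holes filled, is the candidate. k = 2 reflects the
  near-uniform dark background of mammograms; failures are caught downstream.
- **Quality filter** replaces manual visual inspection with three criteria:
  area fraction in [0.08, 0.75], contact with exactly one vertical border,
  and solidity ≥ 0.85. The thresholds are tunable engineering defaults; the
  filter is a stand-in for human judgement, not a claim about it.
- **Fake-label augmentation**: each accepted image becomes five samples —
  the original plus four copies with one bright rectangle (intensity = the
  99th percentile of breast pixels, side 5–20% of the image) placed in the
  background, always disjoint from the mask. Half of the fake labels are
  deliberately placed 1–4 px from the breast boundary: these hard negatives
  are what stop the segmenter from annexing a label that prints next to the
  tissue, which was the dominant failure mode without them. All variants
  keep the original mask, so label pixels are always supervised as
  non-breast.

The segmenter is a UNet (default 3 down/up levels, base 8 channels in the
library, base 4 in the desk-scale experiments; sizes are configurable)
trained with the sum of binary cross-entropy and soft-Dice loss under Adam.
The corpus splits by *source image* so no fake-label variant of a training
image can appear in validation or test. Inference thresholds the probability
map at 0.5, keeps the largest connected component and fills holes; an empty
prediction is returned as-is and callers fall back to the uncleaned image.
Dice/IoU follow the standard set definitions with the empty∩empty case
defined as 1.0 (perfect-agreement convention).

Cleaning zeroes pixels outside the mask, crops to the mask bounding box plus
margin, and resizes to the classifier input.

## Cohorts and splitting

Exclusions drop images labelled BIRADS 0 or 6 (noisy assessments) and every
image of any patient flagged for implants or mis-scans. Splitting is
patient-wise at 70/20/10 with largest-remainder rounding and best-effort
stratification by BIRADS (stabilizes small synthetic cohorts; ties broken by
patient-id sort so the split is a pure function of the seed). Hospitals'
train+validation sets become federated clients; every hospital keeps its own
named test set, and a hospital can participate as a test-only site.

## Classification

The classifier is a small convolutional stack (3 conv+ReLU+maxpool blocks,
global average pooling, linear head; ~6k parameters at default width, far
under the 2M budget that keeps per-round parameter transfer cheap).
Normalization is min/max computed on the training partition only and applied
everywhere, clamping out-of-range test pixels to [0, 1] so a shifted
hospital cannot blow up the input distribution. Evaluation reports
macro-averaged F1 over the classes present in each test set's truth — macro
because BIRADS class frequencies are strongly imbalanced — plus the
confusion matrix.

The documented default hyperparameters (cross-entropy, Adam, batch 10, 100
epochs, learning rate 1e-8) mirror a tuned clinical-scale configuration; the
1e-8 learning rate is impractically small for the desk-scale synthetic runs
in this repository, which use 1e-3 to 3e-3 throughout the tests, examples and
acceptance experiments.

## Federated simulation

FedAvg runs in-process and synchronously: each round the server broadcasts
the global state dict, every client trains its local epochs, and the new
global parameters are the weighted average of client parameters — weights
proportional to client sample counts by default (uniform available), the
weighting question being genuinely ambiguous in practice. The average is
computed as `p₁ + Σ wᵢ (pᵢ − p₁)`, algebraically the weighted mean but
bitwise exact when all clients agree. Two design choices matter for
reproducibility:

- Clients keep their local Adam state across rounds (only parameters are
  broadcast). Combined with epoch shuffles drawn from a (seed, global epoch
  index) stream shared with the centralized loop, a single-client federation
  reproduces centralized training bit for bit — a strong end-to-end check on
  the whole training stack.
- Normalization statistics are computed per client and merged into a global
  min/max before round 1 (the information-exchange mitigation); a
  per-client-only mode exists for the ablation.

The rounds/epochs sweep runs (100, 1), (50, 2) and (20, 5) — all 100 total
local epochs — from a common initial model and tabulates final per-hospital
F1 with per-round traces.

## The harmonization ablation

Two conditions on a deliberately heterogeneous two-hospital cohort
(disjoint raw intensity ranges 50–1050 vs 3000–4095, opposite photometric
conventions, printed labels on 95% and clips on 50% of the first hospital's
images):

- **minimal**: metadata harmonization only; labels and clips remain;
  normalization is per-client.
- **full pipeline**: adds breast-area cleaning (UNet bootstrapped from the
  cohort itself) and globally shared normalization statistics.

Both train the same federated classifier from the same initial weights
(150 patients × 2 images at 64×64, 20 rounds × 5 local epochs, learning
rate 3e-3) and report per-hospital macro F1 — evaluated on each hospital's
held-out validation+test patients and averaged over the last three rounds,
because round-to-round merge noise is substantial at this scale.

Across pilot seeds the worst-hospital F1 improved under the full pipeline in
every run (e.g. 0.43→0.59, 0.44→0.65, 0.52→0.56, 0.32→0.59). The
inter-hospital spread usually shrinks as well, but not always: peripheral
cropping enlarges the breast relative to the frame and therefore also helps
the *clean* hospital, occasionally by more than it helps the artifact-heavy
one. The spread direction should be read as typical, not guaranteed, at this
cohort size.

## The synthetic phantoms

A phantom is a half-elliptical breast attached to one vertical border with
multiplicative smooth-noise texture, `birads − 1` bright lesions whose
brightness grows with the class (0.20 + 0.06·birads above tissue on the
display scale) so the label is a recoverable image property, and artifacts
drawn per hospital profile: background printed labels with glyph texture,
2–5 surgical-clip dots, an implant disk, or a truncated scan. Intensities
are quantized into the hospital's raw range, inverted for MONOCHROME1, and
all randomness flows from one explicit seed.

What the phantoms do **not** model: real parenchymal texture, pectoral
muscle, compression artifacts, the true visual statistics of BIRADS
categories, or realistic artifact frequencies (no published estimates exist;
the rates are free parameters). Passing the synthetic suites therefore
demonstrates that the pipeline's mechanics are correct — metadata handling,
mask bootstrapping, leakage-free splitting, federated bookkeeping, the
direction of the harmonization effect — not that the F1 levels would
transfer to clinical data.

## Numerical choices and problem sizes

All network arithmetic is float32 on a small NumPy engine (im2col
convolutions over BLAS, analytic backward passes verified against finite
differences); merging is exact for identical inputs as noted above.
Experiment sizes — 200 phantoms at 128×128 for segmentation recovery, 300
patients at 64×64 for classifier recovery, 150 patients at 64×64 for the
ablation — are the package's chosen desk-scale study conditions; each runs
in minutes on one CPU core. Degenerate inputs fail loudly everywhere:
constant images cannot be clustered or normalized, empty masks cannot be
cleaned, empty clients abort a federation before round 1.

## Known limitations

- The K-means bootstrap assumes a dark, near-uniform background; digitized
  film with strong vignetting would defeat the quality filter's defaults.
- The UNet and CNN are deliberately small; at clinical resolution both the
  architecture scale and the training schedule would need to grow.
- The federation is simulated in one process: no transport, stragglers,
  secure aggregation or client dropout.
- Empty test splits can occur for hospitals with very few patients; the
  pipeline falls back to evaluating on that hospital's validation patients.
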