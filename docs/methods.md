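# Methods

`nodugrade` grades the semantic characteristics (SCs) of pulmonary
nodules — subtlety, calcification, sphericity, margin, lobulation,
spiculation — as binary low/high labels from CT-like image patches, and
quantifies how each SC relates to the malignancy rating. Because the
package must be testable without a clinical archive, it ships a phantom
generator whose nodules carry known SC levels; every downstream stage
(patch extraction, features, correlation ranking, classifiers, metrics)
is exercised against those phantoms.

## Rating model

Nine SCs follow the LIDC rating scales: 1–5 for most, 1–4 for internal
structure, 1–6 for calcification (6 = calcification absent). Up to four
readers rate each nodule. The consensus is the mean of readers 1 and 2
(reader 1 alone if reader 2 is absent; cases without a complete
reader-1 record are discarded). For correlation analysis, calcification
and internal structure are mapped affinely onto 1–5, endpoints
preserved: `x -> 1 + 4(x-1)/(T-1)`. For grading, each SC consensus is
binarized: high iff `>= 3` on the native scale, except calcification,
which is high iff the rating equals 6. The binarization operates on the
real-valued consensus, so a mean of 2.5 is low.

## Correlation ranking

Pearson's `rho` between each SC consensus and the malignancy rating is
computed from the textbook sum-of-deviations formula; a zero-variance
series yields an explicit undefined marker (NaN) rather than 0 or an
exception. SCs are ranked by `|rho|` descending (ties alphabetical,
undefined last); signed values are kept so that the negative direction
of sphericity and margin remains visible.

## Patch extraction

The consensus region R is the pixelwise AND of every reader's filled
contour polygon (even–odd fill, boundary pixels included). Boxes are
row-major, 0-based, half-open. The tight bounding box of R is expanded
symmetrically on its shorter side into a square (an odd expansion puts
the extra pixel toward the top/left), padded by a 5-pixel margin on all
four sides (clipped at the image border and zero-filled outside), and
the same box crops the grayscale image G and the binary image B. Both
are resized to 64×64 — G bilinearly, B by nearest neighbour so it stays
binary.

## Feature descriptor (72 values, registry 1.0)

* **48 Haralick statistics** — G is quantized to 32 gray levels; for
  each co-occurrence distance d ∈ {1, 2, 3} a symmetric gray-level
  co-occurrence matrix is accumulated over the four classic offsets
  (0°, 45°, 90°, 135°, diagonal displacement (d, d)) and normalized;
  16 statistics are computed per distance with 1-based level indices
  (autocorrelation, contrast, correlation, cluster prominence, cluster
  shade, dissimilarity, energy = angular second moment, entropy in
  bits, homogeneity `sum P/(1+|i-j|)`, maximum probability, sum of
  squares, sum average, sum variance about the sum average, sum
  entropy, difference variance, difference entropy). A constant patch
  returns contrast 0, energy 1, and correlation 0 (variance guard).
* **1 image entropy** — Shannon entropy (base 2) of the 32-level
  histogram of G.
* **13 geometric scalars from B** — centroid offset from the patch
  centre, major/minor axis lengths, eccentricity, orientation, convex
  area, filled area, Euler number, equivalent diameter, solidity,
  extent, and two perimeter estimators (weighted boundary-segment and
  Crofton).
* **7 Hu invariant moments of B**, signed-log transformed
  (`sign(h) log10|h|`, 0 stays 0). The mask is cropped to its bounding
  box first so integer translations are bit-exact no-ops.
* **3 intensity moments of G inside B** — mean, population variance,
  biased Fisher skewness (0 for a constant interior).

## Classifiers

All networks are seeded NumPy implementations; convolutions run as
GEMMs on strided window views of the padded activations (an im2col
fallback computes identical results when no CBLAS symbol is found).

**DBN.** A Bernoulli–Bernoulli restricted Boltzmann machine with energy
`E(v,h) = -a'v - b'h - v'Wh` is trained by CD-1: positive statistics
from the data, negative statistics after one Gibbs alternation
(probabilities for the visible reconstruction, samples for the hidden
layer). Real inputs in [0, 1] are treated as Bernoulli probabilities.
Visible biases start at the data log-odds and the weight update carries
L2 decay 2e-4 — without both, wide visible layers (4–8k units) drive
the hidden layer into saturation and the representation collapses. The
partition function is never computed at scale; for toy models (≤ a
dozen units) an exact enumeration oracle verifies that CD training
raises true log-likelihood. Two 100-unit RBMs are pretrained greedily
(lr 0.02, 30 epochs by default; 10 in the scaled experiments), then the
stack plus a single logistic output is fine-tuned end-to-end with Adam
(lr 3e-4 — larger rates intermittently collapse the sigmoid stack —
batch 16, 100 epochs, enough for both input regimes to reach training
convergence, which is what makes their comparison meaningful).

Input regimes: `dbn1` concatenates the flattened G (scaled to [0, 1])
with the flattened B (8192 visible units); `dbn2` concatenates the
flattened G with the 72 features min–max scaled to [0, 1] by a scaler
fitted on the training split only, held-out values clipped (4168
units).

**MBCNN.** Three branches each receive one of the three consecutive
64×64 slices (centred by −0.5 inside the model). A branch is four
convolution sets of two 3×3 same-padding convolutions (16, 32, 64, 128
kernels) with ReLU, each set followed by 2×2/stride-2 max pooling.
Cross-branch skips: branch 2's set s input is the channel concatenation
of its own set s−1 output with branch 1's; branch 3 additionally
concatenates branch 2's (so its set-2 input has 48 channels). The three
4×4×128 outputs are concatenated, batch-normalized, passed through a
3×3/64 convolution with ReLU (reading of the source description's
"full connection layer with 64 kernels of size 3×3", which only
parses as a convolution), flattened, then dense 128 → dense 2 with
softmax. Training: Adam lr 1e-3, weight decay 1e-3 on weight matrices,
batch 16 (batch 32 leaves too few optimization steps per epoch at
cohort sizes of a few hundred), at most 8 epochs with early stop at
training accuracy 0.995. After training, batch-norm running statistics
are recalibrated with exact moments over (a strided subsample of) the
training set; with few steps per epoch the exponential running averages
lag the evolving features badly enough to corrupt inference-mode
predictions.

## Evaluation

ACC = (TP+TN)/n; REC = TP/(TP+FN) with an undefined marker when no
positive truths exist; AUC by the rank formula
`(Σ ranks_pos − M(M+1)/2)/(MN)` with mean ranks on ties (equal to the
Mann–Whitney statistic and to the fraction of correctly ordered
positive–negative pairs); DSC = 2|A∩B|/(|A|+|B|), defined as 1 for two
empty sets. Cross-validation is stratified fivefold with the nodule as
the grouping unit — all slices, patches and features of a nodule stay
in one fold — with per-class fold sizes differing by at most one; both
training-split and held-out metrics are reported, labelled explicitly.
`Ave` is the arithmetic mean of per-SC accuracies.

## Phantom generator

Each nodule is a star-convex radial function rendered on Gaussian
parenchyma-like noise (mean 0.30, SD 0.05):

* **sphericity** — axis-ratio stretch k ∈ {1.60, 1.45, 1.25, 1.10,
  1.00} for levels 1–5;
* **lobulation** — 2–4 wide sinusoidal bumps, amplitude
  {0, 0.03, 0.14, 0.20, 0.27}·r₀;
* **spiculation** — narrow Gaussian spikes (width 0.20 rad), count
  {0, 2, 6, 8, 10} and amplitude {0, 0.10, 0.32, 0.45, 0.58}·r₀;
* **subtlety** — interior contrast of 2.0 + 1.3·(level−1) background
  SDs (linear in the level; even level 1 stays above the noise floor,
  as for a human reader);
* **margin** — boundary blur with Gaussian sigma
  {2.6, 2.0, 1.0, 0.7, 0.4} px;
* **calcification** — 2·(6−level) bright interior speckles, none at
  level 6 (absent).

Level-to-geometry mappings are monotone and steepest across the 2→3
boundary, where the rating semantics switch from "none/low" to
"marked/high". Slices 2 and 3 re-render the same shape at radius scale
0.9 and 0.8. Reader contours perturb the truth radius with smooth
periodic noise clipped to ±`reader_jitter` (default 1.5 px — the
inter-reader disagreement magnitude is a free choice), so the reader
intersection always sits inside the jitter-dilated truth mask. Internal
structure and texture are generated as ratings only; the grading models
never target them, but the correlation ranking needs all eight SCs.

Cohorts draw the malignancy label Bernoulli(0.5) and shift each SC's
level distribution by label × link strength; default link magnitudes
(spiculation 0.90 down to texture 0.05) make spiculation the strongest
correlate, with sphericity and margin linked negatively. Balanced
grading tasks fix the target SC low (1–2) or high (3–5) and draw the
other characteristics from the empirical rating marginals of a large
multi-reader screening cohort (`RATING_MARGINALS`), under which sharp
margins and conspicuous nodules dominate — as in real screening data —
rather than from uniform levels.

**What the phantoms do not capture:** vessel or pleural attachment,
part-solid and ground-glass texture, inter-slice anatomy changes beyond
isotropic shrinkage, reader biases that correlate across nodules, and
any true 3-D structure. Passing results therefore demonstrate that the
implementation is correct and that the pipeline can recover known
structure, not that these accuracies transfer to clinical data.

## Problem sizes and schedules

The packaged experiments are scaled to a single CPU: correlation
ranking on 500 unrendered cohort nodules; classifier comparisons on a
balanced 600-triplet spiculation task (fivefold, so 480 training
nodules per fold) in the test suite and 300 triplets in the
reproduction script. At these sizes the fivefold MBCNN mean held-out
accuracy lands around 0.92–0.95, DBN2 around 0.92, DBN1 around 0.89 —
the qualitative ordering (MBCNN ≥ DBN2 ≥ DBN1) matches the full-scale
study the package re-implements, while absolute values on phantoms are
not comparable to clinical results.

## Degenerate inputs and tie-breaks

Constant images: GLCM correlation 0, entropy 0, skewness 0. Empty
reader intersections raise a distinct "no consensus" signal so callers
can drop the nodule. A mask that vanishes under nearest-neighbour
downsampling keeps its contract by marking the patch centre pixel. AUC
ties get mean ranks; an all-tied score vector gives 0.5. Fold
re-stratification is attempted once (seed+1) if a training split loses
a class. Box expansion ties go toward the top/left.
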