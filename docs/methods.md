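# Methods

This note documents the models and procedures mammotex implements, the
parameters that matter, the numerical conventions that make results
bit-reproducible, and the design choices made where the method description
left the design open.

## Pipeline overview

The pipeline classifies grayscale mammographic images into the eight
BI-RADS categories in four stages, deliberately without any preprocessing
or segmentation:

1. **Feature extraction** — five texture descriptor families per image,
   concatenated into an 88-vector.
2. **Oversampling** — multiclass ADASYN grows every minority class toward
   the majority count.
3. **Feature selection** — ReliefF weights all 88 features; the top 10 are
   kept.
4. **Classification** — a feedforward network (hidden layers 40-20-10,
   8-way softmax output) trained by Levenberg–Marquardt, with a stratified
   60/20/20 train/validation/test split.

## Texture descriptors (88 features)

All descriptors operate on nonnegative integer images with a known level
count. Images are quantized to 32 gray levels for co-occurrence and
run-length analysis (`floor(pixel * 32 / n_levels_in)`), the standard
texture-analysis compromise between matrix density and contrast
resolution at mammogram scale. Coordinates are row-major, origin top-left,
0-based; the gray index *inside* GLCM/GLRLM statistics is 1-based (the
classical convention, which keeps 1/i² terms finite).

### GLCM (22 features)

Co-occurrence counts `G[i,j]` of pixel pairs at displacement `(dr,dc)`,
built symmetric and normalized, averaged over the four distance-1
directions 0°/45°/90°/135°. The 22 statistics (p = normalized matrix,
indices i,j = 1..N, marginals p_x, p_y, means μ_x, μ_y, standard
deviations σ_x, σ_y, and the sum/difference marginals p_{x+y}, p_{x−y}):

| feature | formula |
|---|---|
| autocorrelation | Σ i·j·p |
| contrast | Σ (i−j)²·p |
| correlation | (Σ i·j·p − μ_xμ_y)/(σ_xσ_y) |
| cluster prominence | Σ (i+j−μ_x−μ_y)⁴·p |
| cluster shade | Σ (i+j−μ_x−μ_y)³·p |
| cluster tendency | Σ (i+j−μ_x−μ_y)²·p |
| dissimilarity | Σ \|i−j\|·p |
| energy | Σ p² |
| entropy | −Σ p·log₂p |
| homogeneity | Σ p/(1+\|i−j\|) |
| inverse difference moment | Σ p/(1+(i−j)²) |
| maximum probability | max p |
| sum of squares: variance | Σ (i−μ_x)²·p |
| sum average | Σ k·p_{x+y}(k) |
| sum variance | Σ (k−SA)²·p_{x+y}(k) |
| sum entropy | −Σ p_{x+y}·log₂p_{x+y} |
| difference variance | variance of p_{x−y} |
| difference entropy | −Σ p_{x−y}·log₂p_{x−y} |
| IMC 1 | (HXY−HXY1)/max(HX,HY) |
| IMC 2 | √(1−exp(−2(HXY2−HXY))) |
| inverse difference normalized | Σ p/(1+\|i−j\|/N) |
| inverse difference moment normalized | Σ p/(1+((i−j)/N)²) |

Conventions: 0·log 0 := 0 everywhere; the entropy-style features are in
bits (log₂) while the information measures of correlation use natural logs
internally, as in their classical definitions. Degenerate denominators
(constant image ⇒ σ = 0, or zero marginal entropy) define the statistic as
0, so a constant image yields a finite vector. The published description of
this feature set garbles several names in translation; the list above is
the canonical Haralick/Soh/Clausi-style 22-statistic set, with the
homogeneity pair (|i−j| and (i−j)² denominators) split into two entries and
cluster tendency completing the count.

### LBP (10 features)

8-neighbor local binary pattern at radius 1: each interior pixel receives
code Σ_p s(g_p − g_c)·2^p with s(x) = 1 iff x ≥ 0 (ties count as 1) and
neighbors ordered counterclockwise starting east. Border pixels are
excluded. The feature is the normalized 10-bin rotation-invariant uniform
histogram: codes with at most two circular 0/1 transitions map to their
set-bit count (bins 0–8), all others to a single non-uniform bin.

### LBGLCM (22 features)

Pure composition: the LBP code image (values 0–255) is requantized to 32
levels and passed through the same 22 GLCM statistics. No new mathematics;
the value is that second-order structure of the *pattern* image differs
from that of the intensity image.

### GLRLM (7 features)

Maximal runs of equal gray value along each direction are counted into
P(i,j) (gray level i, run length j). With n = total runs, n_p = pixels:

SRE = (1/n)ΣΣ P/j², LRE = (1/n)ΣΣ j²P, GLN = (1/n)Σ_i(Σ_j P)²,
RLN = (1/n)Σ_j(Σ_i P)², RP = n/n_p, LGRE = (1/n)ΣΣ P/i²,
HGRE = (1/n)ΣΣ i²P.

These are the canonical Galloway/Chu forms (the published equation block
for this set is typographically corrupted — summation limits and
normalizers are mangled — so the canonical forms are used). Features are
averaged over the four directions. Invariant: Σ_i Σ_j j·P(i,j) equals the
pixel count, since runs partition pixels.

### SFTA (27 features)

Multi-level Otsu computes nt = 5 thresholds; the image is decomposed into
2·nt − 1 binary images: nt − 1 band images (t_k < pixel ≤ t_{k+1}) from
contiguous threshold pairs, then nt upper images (pixel > t_k), both in
ascending threshold order. Each binary image contributes three features:
the box-counting fractal dimension of its region border, the mean original
gray level over the foreground, and the foreground pixel count. An empty
binary image contributes (0, 0, 0) rather than NaN.

Numerical conventions:

- **Multi-level Otsu** is solved *exactly* by dynamic programming over the
  gray-level histogram (minimizing total within-class weighted sum of
  squares, equivalent to maximizing between-class variance), O(nt·L²) on
  the occupied bins. Ties resolve to the smallest threshold vector. A
  threshold t places pixel v in the lower class iff v ≤ t. Inputs with
  more than 256 levels are first quantized to 256 for this search.
- **Borders** are foreground pixels with at least one in-image background
  4-neighbor; a region flush against the image edge has no border there
  (so a half-plane's border is a straight line of dimension ≈ 1).
- **Box counting** uses dyadic box sizes {1, 2, 4, …, min(dim)/2} anchored
  at (0,0); the dimension is the least-squares slope of log(occupied boxes)
  vs log(1/size), 0 for empty or degenerate inputs.

### Degenerate images

`extract_features` on an image with too few distinct levels for the SFTA
threshold search (e.g. a constant image) emits zeros for the SFTA block so
the 88-vector stays finite; `otsu_multilevel` itself raises, preserving its
own contract.

## ADASYN oversampling

For each minority class (any class below the majority count; threshold
d < 1.0), the budget is G = round((m_l − m_s)·β) with β = 1. Each minority
sample gets difficulty weight r_i = (fraction of its K = 5 nearest
neighbors *over the whole dataset* with a different label), normalized;
G is allocated by largest-remainder rounding (ties to the lower index, so
Σg_i = G exactly, and larger weights never receive fewer synthetics).
Synthetics interpolate s = x_i + λ(x_zi − x_i), λ ~ U(0,1), with x_zi drawn
from the seed's K nearest *same-class* neighbors — so every synthetic is a
convex combination of two same-class originals. Neighbor searches use
Euclidean distance on features standardized to zero mean/unit variance
(preventing large-magnitude features from dominating); synthesis happens in
the original feature space. Singleton classes duplicate their seed with a
logged warning. Per-class RNG streams derive from (seed, label), so output
is deterministic and independent of class processing order.

On the canonical 67/220/24/13/8/21/50/8 distribution with β = 1 this
generates 153/196/207/212/199/170/212 synthetics (total 1760 rows). The
originally published per-class generated counts disagree with their own
G = (m_l − m_s) arithmetic; the mechanism, not those counts, is
reproduced.

## ReliefF selection

diff(A, I₁, I₂) = |I₁[A] − I₂[A]| / range(A), with 0 for zero-range
(constant) attributes — this makes weights scale-invariant and bounded in
[−1, 1]. Instance distance is the Manhattan sum of per-attribute diffs.
Every instance is visited once in index order (m = n; the randomized
variant is available via config but the full deterministic sweep is the
default, chosen for reproducibility). For visited instance T: k = 3
nearest hits (same class, excluding T) lower W by diff/(m·k_used); for each
other class C, the k nearest misses raise W by
[P(C)/(1 − P(class(T)))]·diff/(m·k_used), the standard multiclass
prior-weighted extension. Classes smaller than k+1 use as many neighbors
as exist (logged), dividing by the count actually used. Ranking sorts by
descending weight, ties to the lower index; the default selection keeps
the top 10 of 88. `weight_curve` reports stratified cross-validated
accuracy as a function of the number of top-ranked features for choosing
n_select empirically.

## Levenberg–Marquardt network

Architecture input→40→20→10→8: tanh hidden layers, softmax output. (A
config flag `layer1_linear` reproduces the literal "linear first layer"
reading of the source description; the default is tanh, since a linear
first layer merely composes with the second layer's weights.) Weights are
initialized Nguyen–Widrow-style — seeded uniform rows rescaled to
magnitude 0.7·S^(1/R) — with zero biases.

Training minimizes the sum-squared error of residuals e = t − a over
one-hot targets. LM requires a residual structure, which cross-entropy
lacks; multinomial cross-entropy is therefore computed per epoch as a
monitoring metric only. The Jacobian J = ∂e/∂w is computed by
per-output-unit backpropagation (seed ∂e_{s,o}/∂z_j = −a_o(δ_{oj} − a_j)
at the softmax input); J is never materialized for the full training set —
JᵀJ and Jᵀe are accumulated over 256-sample chunks. The step solves
(JᵀJ + μI)Δw = Jᵀe by Cholesky factorization and applies w ← w − Δw;
a singular system at small μ is handled by raising μ and retrying, never by
crashing. Steps that lower the SSE are accepted (μ ← μ/10); rejected steps
raise μ (×10). Stopping: max_epochs, μ > 1e10, ‖Jᵀe‖ < 1e-7, or 6
consecutive validation-error increases; the best-validation parameters are
restored at the end. Defaults μ₀ = 1e-3, mu_inc = 10, mu_dec = 0.1,
max_epochs = 1000, patience = 6 are the conventional LM settings.

The 60/20/20 split is stratified per class (proportions within ±1 sample)
and seeded. Prediction is the argmax class probability, ties to the lowest
class label.

## Evaluation

Confusion matrix rows = actual, columns = predicted. One-vs-rest per class:
TP = diagonal, FP = column − TP, FN = row − TP, TN = total − TP − FP − FN.
Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN), accuracy (TP+TN)/total, misclassification (FP+FN)/total,
F1 = 2pr/(p+r). Pooled: micro F1 (F1 of summed TP/FP/FN; for single-label
multiclass data this equals trace/total, i.e. overall accuracy — asserted
as a property test), macro F1 (unweighted mean), weighted F1
(support-weighted mean). Zero denominators report 0 with a logged warning.
Percentages are printed to 1–2 decimals; raw ratios keep full precision.

## Synthetic data

**Texture images** are Gaussian random fields: seeded white noise smoothed
by a Gaussian kernel at a class-specific correlation length (0.5–8 px
across the eight classes), standardized, scaled by a class contrast
(30–55), shifted to a class base level (90–160), and quantized to 8 bits.
Class counts default to the canonical 411-image distribution
67/220/24/13/8/21/50/8. Random fields expose exactly the second-order
statistics the descriptors measure, so classes are separable by
construction (correlation lengths 1 vs 8 differ in mean GLCM contrast by
far more than 2×). What they do **not** emulate: anatomy, lesion
morphology, scanner noise, or any clinically meaningful BI-RADS structure
— passing tests demonstrate that the pipeline machinery works and is
sensitive to texture statistics, not that the published clinical accuracy
transfers to real mammograms.

**Tabular data** is a desk-scale surrogate for the 88-feature table:
10 informative features per class-mean at a distinct random ±1 hypercube
corner scaled by class_sep/2, plus 78 label-independent N(0,1) noise
features. At the default class_sep = 4 the classes are cleanly separable —
this is a correctness regime, not a difficulty benchmark.

### Evaluation protocol caveat

Matching the methodology it reimplements, the pipeline oversamples the
*full* feature table and splits afterward, so synthetic test rows can be
interpolations of training rows. This leaks neighborhood information and
inflates balanced-run scores relative to a split-first protocol; it is kept
because reproducing the method is the point, and it is called out here so
nobody mistakes the balanced-run numbers for unbiased generalization
estimates.

### Study conditions used by the test suite

- End-to-end accuracy: class_sep 4, canonical class counts, top-10
  features, 3 seeds; networks train with max_epochs = 15 (LM converges on
  this separable problem in ~10 epochs; the cap is a convergence choice,
  the early-stopping rules remain active).
- ADASYN minority-recall improvement: class_sep 2 — the
  moderate-separation regime where imbalance demonstrably hurts the
  unbalanced run (mean minority recall ~0.6–0.8 there vs ~0.99 balanced).
  At class_sep 4 the unbalanced run is already near-perfect and the
  comparison would be vacuous.
- The class_sep monotonicity sweep uses equal counts of 20 per class
  (already balanced, so the oversampler is a no-op) to keep 12 training
  runs cheap.

## Known limitations

- Only P = 8, R = 1 LBP is implemented (the configuration the 88-feature
  layout requires).
- GLCM statistics assume the matrix fits densely (32² default); level
  counts in the thousands would need a sparse path.
- LM memory scales with the square of the parameter count (JᵀJ is dense);
  the default 10-input network has 1 558 parameters, comfortably small,
  but very wide inputs would require a different optimizer.
- The DICOM writer/reader handles single-frame monochrome secondary
  captures — enough for fixtures and typical exported mammograms, not the
  full DICOM zoo.
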