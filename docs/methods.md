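# Methods

## Problem and pipeline

`polarforest` models an optical-diagnostics workflow for skin tissue: a
sample's polarization transfer is measured as a 4×4 Mueller matrix, the 15
m11-normalized elements are used as features, and a random forest separates
four tissue classes — basal cell carcinoma (BCC), squamous cell carcinoma
(SCC), melanoma and normal skin. The package implements the four stages as
separate modules:

1. **polarimetry** — forward Stokes propagation `s_out = M s_in` and exact
   reconstruction of all 16 elements from six canonical probe states
   (linear 0°, 45°, 90°, 135°; right/left circular). Columns of `M` come
   from half-sums and half-differences of the paired output vectors:
   col 1 = ½(S₀ + S₉₀), col 2 = ½(S₀ − S₉₀), col 3 = ½(S₄₅ − S₁₃₅),
   col 4 = ½(S_RHC − S_LHC).
2. **synthetic** — a class-conditional generator of labeled feature tables
   (real tissue measurements are not public).
3. **forest** — a from-scratch CART/random-forest classifier with Gini
   splitting and impurity-decrease feature importance.
4. **training / evaluation** — oversampling, repeated stratified 10-fold
   cross-validation, grid search; confusion matrix, precision/recall/F1,
   one-vs-rest ROC AUC.

## Synthetic data model

Each physical sample is described by nine optical parameters: linear
diattenuation `d ∈ [0,1]` with orientation `θ_D`, circular diattenuation
`cd`, linear retardance `δ` with fast axis `θ_R`, optical rotation `ψ`
(all angles in radians), and a depolarization diagonal `(a, b, c) ∈ (0,1]³`.
The sample matrix is composed in the fixed forward order

    M = M_depol(a,b,c) · M_ret(δ, θ_R, ψ) · M_diat(d, θ_D, cd),

the conventional polar-decomposition order; any physically valid
composition would do for a generator, and this one keeps `m11 = 1` and is
easy to invert mentally when writing tests.

**Hierarchy.** Parameters are drawn per *sample* (σ = 0.5 × base spread),
perturbed per *slice* (0.4 ×) and again per *point* (0.05 ×), with the base
per-parameter spread `[0.03, 0.08, 0.03, 0.10, 0.08, 0.05, 0.04, 0.04,
0.04]` in the parameter order above. This mirrors the study design the
counts come from: samples cut into 4–6 slices, each measured at 4–6
points. The default per-class totals are the reference counts
(train 282/231/52/42, test 30/23/3/6 for BCC/SCC/melanoma/normal), with
train/test split by sample and one held-out sample per class. The slice
allocator prefers the 4–6 × 4–6 design and relaxes downward only where a
small held-out sample (e.g. 3 melanoma test vectors) makes it infeasible.

**Class means.** The four class parameter means are artifact choices, not
biology: each class is dominated by a different optical effect (normal =
weakly polarizing; BCC = strong linear retardance; SCC = strong
diattenuation at a rotated axis; melanoma = strong depolarization plus
circular effects) so the means are far apart and deliberately not
collinear in parameter space. They were calibrated against three stated
targets: element magnitudes of similar size across classes with
class-distinct distributions, the within-slice variability bands below,
and recoverability of the labels by the forest (held-out accuracy ≥ 0.9 at
the default separation). A `class_separation` dial scales all class means
toward their pooled mean; at 0 the classes are statistically identical and
accuracy must fall to chance.

**Noise model.** Measurement noise enters at the Stokes level, before
reconstruction. For each state pair feeding one reconstructed column
(0°/90°, 45°/135°, RHC/LHC) the two outputs receive a *common-mode* and a
*differential* Gaussian perturbation per component — physically, a shared
drift between the paired acquisitions versus a state-dependent error. The
reconstruction maps the common mode of the 0°/90° pair onto column 1 and
the differential modes onto columns 2–4, so the model's 4×4 `sigma` matrix
is exactly the standard deviation induced on each reconstructed element.
This structure is forced by the target variability pattern: m21 and m22
are the sum and difference of the *same* two raw measurements, so
independent per-component noise would give them equal variance, yet the
wide band contains m21 and not m22. Default sigmas: 0.050–0.075 for the
wide elements m12, m13, m14, m21, m24, m34; 0.004 for the rest (0.003 for
m11, whose noise propagates into every feature through normalization).
With these defaults the mean-over-slices within-slice standard deviation
lands in [0.03, 0.1] for the wide elements and below 0.01 for the others.

**What the generator does not emulate.** Real element distributions
(skewness, outliers, inter-element correlations induced by shared tissue
microstructure), wavelength dependence, calibration drift, and any genuine
biological contrast. Passing tests therefore demonstrate that the pipeline
recovers class structure *of this generative form* at the study's sample
sizes — not that the classifier would reach the same accuracy on tissue.

## Classifier

Trees are grown greedily. At each node a fresh random subset of
`floor(sqrt(15)) = 3` features is drawn; candidate thresholds are midpoints
of consecutive distinct sorted values; the split maximizing the Gini
impurity decrease

    n_ij = w_j G_j − w_jL G_jL − w_jR G_jR,   G = 1 − Σ_i p(c_i|t)²,

wins, where `w_j` is the fraction of the tree's training instances
reaching node `j`. Growth stops at purity, depth 14 (default), node size
< 2, or when no split has positive decrease; a leaf predicts its majority
class. Each of the 220 trees (default) trains on a bootstrap resample of
size n. Prediction is one vote per tree; vote fractions are the class
scores used for ROC. Per-tree importance is
`f_i = Σ_j n_ij / Σ_k n_ik` over internal nodes, forest importance is the
mean of `f_i` over trees, renormalized to sum to 1; a tree with no
internal node contributes zeros.

Numerical choices: impurity decreases below 1e−12 are treated as zero
(genuine decreases on integer counts are ≥ 1/n³); ties between equally
good splits go to the lowest feature index, then the lowest threshold;
plurality ties in voting and leaf labeling go to the first class in the
fixed case-insensitive alphabetical order (BCC < melanoma < normal < SCC).
All randomness flows from a single `numpy` Generator per fit, so equal
seeds give identical forests.

## Training workflow

Class counts are balanced by random duplication of minority-class rows up
to the majority count. Faithfully to the workflow being emulated — and
flagged with warnings, with flags to disable — oversampling happens
*before* fold splitting (duplicates can leak across CV folds) and is also
applied to the held-out test partition. Grid search scores every
(n_trees, depth) point by the mean validation accuracy of stratified
k-fold CV (k = 10, 3 repetitions, each repetition reshuffled with a
derived seed); ties go to fewer trees, then smaller depth. The shipped
final configuration is 220 trees at depth 14.

## Evaluation

Confusion matrices use the fixed class order above. Per-class precision,
recall and F1 are one-vs-rest; zero-denominator cases report 0 with a
warning. Presentation values are rounded to two decimals, ties away from
zero (so 111/120 = 0.925 prints as 0.93); raw values are always kept in
machine output. One-vs-rest AUC uses thresholds at the distinct observed
vote fractions and trapezoidal integration, which equals the Mann–Whitney
statistic with ties credited ½; classes absent from the truth get a
missing AUC and are excluded from the unweighted mean with a warning.

## Calibration diagnostics and problem sizes

Two calibration checks use a dedicated *balanced* layout (6 training and
24 held-out samples per class, ~25/6 points each) rather than the
reference counts: with only one held-out sample per class, predictions are
near-perfectly correlated within the sample, so chance-level accuracy
concentrates on {0, 0.25, 0.5, …} and no tolerance around 0.25 is
meaningful. On the balanced layout, `chance_level_accuracy` averages three
independent zero-separation replicates (the replicate mean is the stable
statistic; single replicates have σ ≈ 0.04). The reference-implementation
cross-check compares replicate-averaged held-out accuracy of this forest
against scikit-learn's at equal hyperparameters on 200-instance datasets
at partial (0.25) separation, where accuracy is mid-range and the
comparison is informative; single-replicate gaps of ±0.1 arise from
bootstrap randomness alone.

## Known limitations

- The forest is pure Python/NumPy; fitting 220 depth-14 trees on ~1100
  instances takes about a second, but the full 100 × 19 grid search at
  repeated 10-fold CV is expensive and is therefore exposed behind an
  explicit flag with a reducible grid.
- No out-of-bag error, permutation importance, pruning, or categorical
  features; impurity importance is known to prefer features with many
  distinct values, which is acceptable here because all 15 features are
  continuous and on comparable scales.
- Physicality of reconstructed matrices is warned about, not enforced;
  noisy measurements may be slightly unphysical by design.
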