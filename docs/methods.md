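# Methods

`ldwcnn` implements a hybrid classification-and-recommendation pipeline for
small tabular clinical datasets (heart, liver, kidney), combining linear
discriminant analysis (LDA) for supervised feature extraction, a grey wolf
optimizer (GWO) for wrapper feature selection and hyperparameter tuning, a
compact convolutional neural network (CNN) classifier, and a
reference-range-based severity recommender. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Pipeline

Stages run in a fixed order: read/simulate → impute → stratified 60/20/20
split → z-score normalisation + one-hot encoding → LDA projection → GWO
feature selection → GWO hyperparameter tuning → CNN training → test-set
classification → severity recommendation → metrics. Disabling a stage
(`select_iterations=0`, `tune_iterations=0`, or the `cnn_baseline` variant,
which feeds raw normalised features to the CNN) bypasses it without
reordering the others. Every stochastic step takes an explicit seed from the
config, so a report can be replayed bit-for-bit from its own provenance
block (single-threaded execution assumed).

### Preprocessing

Missing cells (`'?'` or empty in CSV/ARFF) are filled by column mean
(continuous) or column mode (categorical); a `drop_rows` strategy is
available for tables where discarding incomplete rows is affordable. The
default is imputation because the clinical tables this targets are small
(hundreds of rows). Normalisation statistics and imputation statistics are
fit on the training split only and applied to validation/test — the
leakage-free choice. Categorical features are one-hot encoded with the
category list frozen from the training split; unseen categories map to the
all-zero row. Splitting is stratified by class via per-class
largest-remainder allocation, which guarantees each part's class count is
within one row of the exact proportional target.

### LDA feature extraction

Per-class means μ_k, within-class scatter S_w = Σ_k Σ_{n∈C_k}
(x_n−μ_k)(x_n−μ_k)ᵀ and between-class scatter S_B = Σ_k N_k (μ_k−μ)(μ_k−μ)ᵀ
feed the generalized eigenproblem S_w⁻¹ S_B v = λ v, solved with the
symmetric-definite solver. At most C−1 eigenvalues are nonzero for C
classes, so the projection keeps K ≤ min(d, C−1) components (pipeline
default: exactly min(d, C−1), i.e. one discriminant dimension for the binary
liver/kidney problems and four for five-grade heart severity).

Numerical choices: a ridge `1e-6 · trace(S_w)/d` is added to S_w by default
because n ≤ d makes S_w singular on tiny tables; `ridge=0` raises instead of
silently regularising. Eigenvectors are unit-norm with the
largest-magnitude component made positive (reproducible sign), and
eigenvalue ties keep the solver's order under a descending stable sort.

### Grey wolf optimizer

Canonical formulation: for each wolf and each leader ℓ ∈ {α, β, δ}, fresh
per-dimension uniforms r1, r2 give A = 2a·r1 − a and C = 2·r2; the candidate
is x_ℓ − A·|C·x_ℓ − x| and the new position is the mean of the three
candidates, clamped to the box bounds. The control scalar a decays linearly
from 2 to 0 over the iteration budget; termination is the fixed budget only.
Leaders are the best three solutions seen so far, making the best-so-far
curve monotone. Maximization objectives are negated internally.

Feature selection runs the continuous optimizer with sigmoid decoding (bit j
set iff σ(x_j) > 0.5, strict; all-zero masks repaired to the
largest-sigmoid bit) and minimises `validation_error + λ_s · |mask|/dim`
with λ_s = 0.01 — a small explicit sparsity/accuracy trade-off. Tuning
searches learning rate on a log10 scale in [1e-4, 1e-2] and dropout in
[0.2, 0.7], decoding integers by rounding, and returns the candidate with
the highest validation accuracy encountered. Both wrappers evaluate
candidates by training reduced-epoch CNNs (selection: 10 epochs, tuning: 15,
patience 3); the pipeline's default budgets (5 wolves × 5 iterations for
selection, 4 × 3 for tuning) keep a full run to seconds on one CPU while
still exercising the search. An evaluator failure penalises that wolf with
the worst observed fitness rather than aborting.

### CNN classifier

Features are embedded row-major into the smallest square single-channel
grid (zero-padded tail); a 1×d grid recovers 1-D convolution behaviour. The
architecture is conv(32, 3×3, pad 1) + ReLU → max-pool 2×2 → conv(64, 3×3,
pad 1) + ReLU → max-pool → flatten → dropout 0.5 → dense → softmax, with an
optional dense hidden layer. Each stage's spatial size follows
floor((N + 2·PD − K)/ST) + 1; pooling is applied only where the spatial size
is at least the window, so degenerate grids (a 1×1 embedding of a single
discriminant feature) pass through rather than collapsing. Training
minimises categorical cross-entropy with Adam at learning rate 0.001 for up
to 50 epochs, early-stopping on validation loss with patience 5 and
restoring the best weights (patience 0 stops at the first non-improving
epoch; `patience=None` disables the rule). The implementation is plain
numpy — forward and backward passes, Adam, and dropout are written in the
package — which keeps runs fully seeded and dependency-light at the tiny
grid sizes involved.

One model is trained per disease dataset (the schemas differ); a thin
registry routes records by `dataset_id`.

### Severity recommendation

Published reference ranges are shipped as an editable YAML config: AST
normal ≤ 35 IU/L (high ≤ 40, very high above), ALT normal ≤ 45 (high ≤ 56),
serum creatinine 60–120 µmol/L male / 50–110 female, potassium medium
5.3–5.5 mmol/L, high (5.5, 6], very high above 6, blood pressure low at
≤ 90/60 and high at ≥ 140/90, cholesterol normal ≤ 129 mg/dL, borderline
130–159, high 160–189, very high ≥ 190. The printed potassium bands were
internally inconsistent at the source (the same 5.3–5.5 interval appeared
for two tiers), so the monotone repair above is declared in the config and
overridable; cholesterol below 100 is treated as normal since the source
bands leave it unaddressed.

The severity level is `probability + 0.5 · (risky markers)/(evaluated
markers)`, where "risky" means very-high or out-of-range-low bands; the
boost is capped at 0.5 so the level lies in [0, 1.5]. This combination rule
is the package's own construction — the recommendation tiers it feeds are
fixed, but how a level above 1 arises from a classifier was otherwise
unspecified. Tiers: a no-disease verdict is always "Patient is normal";
otherwise negative levels get no recommendation, [0, 0.5) → exercise,
[0.5, 1) → visit a doctor, ≥ 1 → hospitalize. The boundary levels 0.5 and
1.0 follow the worked prediction table (which maps 0.5 to "visit a doctor"
and 1 to hospitalization) rather than the looser pseudocode thresholds —
worked examples outrank pseudocode, and it is the safer clinical direction.
The heart schema carries only systolic pressure, so the diastolic slot is
held at its normal reference value during banding; the kidney schema has no
sex column, so the wider male creatinine range applies.

### Evaluation

Confusion counts are one-vs-rest per class; accuracy is pooled over those
counts and sensitivity/specificity/precision/F-score are macro-averaged,
with zero-denominator classes excluded (and logged). This averaging rule is
a declared choice — a single sensitivity number for a multi-class system
requires one. RMSE is over the (sample, class) cells of the softmax matrix
against the one-hot truth; a class-index variant sits behind a flag.
Cross-validation uses stratified folds; all preprocessing (imputation
statistics, normalisation, LDA) is re-fit inside each training fold.

## Synthetic data

The generator emulates the three public UCI schemas: 13 Cleveland heart
attributes (binary or five-grade severity label), 10 ILPD liver attributes
at 70% positive prevalence, and 22 mixed CKD attributes (prevalence default
0.40, configurable — the public file's composition differs, so no default is
claimed to match it). Continuous features are class-conditional Gaussians
whose between-class mean separation scales with an effect size d (d = 0
makes the class distributions identical, the null condition used in tests);
categorical features get per-class log-odds shifts scaled the same way.
Markers with published reference ranges are centred on their normal band so
healthy rows band as normal. Missingness is injected completely at random
(MCAR) — no informative-missingness mechanism is modelled.

What passing tests therefore show: the pipeline recovers planted
class-conditional mean separation, respects the null, and is reproducible.
What they do not show: performance on real clinical data, which has
correlated features, non-Gaussian marginals, informative missingness, and
label noise — none of which the generator produces.

## Problem sizes

The default test and acceptance runs use 300–600 synthetic rows, 10–22
features, GWO budgets of ≤ 25 candidate evaluations per pass, and CNNs of
two conv layers on grids of 1×1 to 5×5 cells, chosen as representative of
the target datasets (303/583/400 rows) while keeping full runs to seconds.
The GWO convergence benchmark (sphere, 5-D, 20 wolves, 100 iterations)
reaches ~1e-19 median best fitness over 10 seeds.

## Known limitations

- With binary labels the LDA stage reduces to a single discriminant
  feature, making the downstream feature-selection pass trivial; it becomes
  meaningful for the five-grade heart label or when `lda_k` is raised.
- The CNN is an in-package numpy implementation: single-threaded, CPU-only,
  no augmentation, and limited to the two-conv template plus an optional
  hidden layer.
- The recommendation engine's risk boost is a simple capped fraction; it is
  a transparent, documented rule, not a calibrated clinical score.
- Ratio pairs other than 60/20/20 (e.g. 75/25) are supported as harness
  options, but no particular split is claimed canonical.
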