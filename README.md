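# ldwcnn

A hybrid **L**inear **D**iscriminant + grey-**W**olf-optimized **CNN**
pipeline for multi-disease tabular clinical data, with a reference-range
severity recommender. It targets the small public heart, liver and kidney
datasets (hundreds of rows, mixed continuous/categorical features, `'?'`
missing markers) and the clinicians/ML practitioners who want a fully
seeded, inspectable decision-support baseline on such data.

## The method

1. **Preprocess** — mean/mode imputation, stratified 60/20/20
   train/validation/test split, per-feature z-scoring and one-hot encoding
   (statistics fit on the training split only).
2. **LDA feature extraction** — per-class means μ_k, within-class scatter
   S_w = Σ_k Σ_{n∈C_k}(x_n−μ_k)(x_n−μ_k)ᵀ and between-class scatter
   S_B = Σ_k N_k(μ_k−μ)(μ_k−μ)ᵀ feed the generalized eigenproblem
   S_w⁻¹S_B v = λv; the K ≤ C−1 leading eigenvectors form the projection.
3. **Grey wolf optimization** — candidate solutions move toward the three
   best wolves (α, β, δ) with decaying randomized coefficients
   (A = 2a·r₁ − a, C = 2r₂, step x_ℓ − A·|C·x_ℓ − x| averaged over
   leaders). A continuous pack with sigmoid decoding does wrapper feature
   selection (fitness = validation error + λ_s·|mask|/d); a second pass
   tunes the CNN learning rate (log scale) and dropout by validation
   accuracy.
4. **CNN classification** — features embed row-major into a small square
   grid; conv(32, 3×3) + ReLU → max-pool → conv(64, 3×3) + ReLU → max-pool
   → flatten → dropout 0.5 → dense → softmax, trained with Adam (lr 0.001)
   and categorical cross-entropy, up to 50 epochs with early stopping.
5. **Recommendation** — clinical markers are banded against published
   reference ranges (AST/ALT, serum creatinine and potassium, blood
   pressure and cholesterol); the severity level
   `probability + 0.5·(risky markers)/(evaluated markers)` maps to tiers:
   exercise `[0, 0.5)`, visit a doctor `[0.5, 1)`, hospitalize `≥ 1`.
6. **Evaluation** — one-vs-rest confusion counts, macro-averaged
   sensitivity/specificity/precision/F-score, probability-vs-one-hot RMSE,
   and stratified k-fold cross-validation with per-fold refitting.

A synthetic-data module generates class-conditional tables that mirror the
three dataset schemas (effect size d scales class separation; d = 0 is the
null), so the whole pipeline is testable without downloads. See
`docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
import json
import ldwcnn as L

cfg = L.PipelineConfig(schema="liver", n=600, effect_size=1.5,
                       missing_rate=0.05)
report = L.run_pipeline(cfg)
m = report.metrics
print(json.dumps({
    "accuracy": round(m.accuracy, 4), "sensitivity": round(m.sensitivity, 4),
    "specificity": round(m.specificity, 4), "rmse": round(m.rmse, 4),
    "selected_features": int(sum(report.selected_mask)),
    "tuned_learning_rate": round(report.tuned_spec.learning_rate, 6),
    "tuned_dropout": round(report.tuned_spec.dropout_rate, 3)}, indent=2))
```

prints

```json
{
  "accuracy": 0.975,
  "sensitivity": 0.973,
  "specificity": 0.973,
  "rmse": 0.1313,
  "selected_features": 1,
  "tuned_learning_rate": 0.004523,
  "tuned_dropout": 0.405
}
```

i.e. on a 600-row synthetic liver cohort with moderate class separation
(d = 1.5, 70% positive prevalence, 5% missingness), the pipeline classifies
97.5% of the held-out test rows correctly; the binary problem collapses to
one LDA discriminant feature, and GWO settled on a learning rate of
~4.5e-3 with dropout ~0.4. Each test patient also receives a recommendation
record:

```json
{"id": 0, "disease": "liver", "level": 1.25, "tier": "hospitalize",
 "message": "Need to get hospitalized and have proper treatment"}
{"id": 3, "disease": "none", "level": 0.165, "tier": "normal",
 "message": "Patient is normal"}
```

The same run is available from the shell:

```sh
ldwcnn simulate --schema liver --n 600 --effect-size 1.5 --seed 0 liver.csv
ldwcnn run --config config.yaml --out results/
ldwcnn cv --config config.yaml --k 10
```

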