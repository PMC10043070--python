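# dualpet

Dual-phase amyloid-PET classification of Alzheimer's disease (AD) versus
cognitively normal (CN) subjects.

A single amyloid-PET reading disagrees with the clinical picture in a
sizeable minority of patients: amyloid-positive CN and amyloid-negative AD
subjects both exist. Early-phase florbetaben (FBB) uptake, acquired in the
first 20 minutes after injection, behaves as a perfusion surrogate and
carries information about neuronal injury that the conventional delay-phase
(amyloid-load) image does not. `dualpet` implements a classifier that fuses
both phases and everything needed to study it end to end:

- **Feature extraction** from template-space NIfTI volumes: atlas labels are
  merged into six cortical target regions (frontal, temporal, parietal,
  occipital, anterior and posterior cingulate) plus a cerebellar reference;
  outputs are a 6 × 27 regional time-activity curve (TAC, each frame
  normalized to the cerebellar mean, i.e. SUVr) and a 6 × 1 delay-phase mean
  SUVr vector, with the 2–7 min static early image as an intermediate.
- **The aggregated classifier.** TACs enter a two-layer LSTM (hidden width
  D = 6, layer-normalized); delay SUVr enters a four-layer feed-forward
  encoder. With phase features h₁, h₂ and the first aggregated feature
  h′ = FC(concat(h₁, h₂)), a phase-attention layer computes

      eᵢ = tanh(xᵢ W + bᵢ),   xᵢ = concat(hᵢ, h′)
      a  = softmax(e),        C = Σᵢ aᵢ hᵢ

  and the AD positivity score is the AD-class softmax probability of
  FC(concat(C, h′)). Training: cross-entropy + L2 (0.01), Adam, dropout 0.2,
  early stopping on validation loss. Single-phase ablations (early-only,
  delay-only) share the recipe.
- **Relevance maps**: first-order Taylor attribution (gradient × input) of
  the AD logit with respect to each TAC cell, with mean-composite profiles
  over regions or time.
- **Baselines**: linear SVM, depth-2/1000-tree random forest, and a plain
  two-hidden-layer FFN, all on the identical splits and scaling.
- **Evaluation**: stratified 0.6/0.1/0.3 splits over diagnosis × amyloid
  reading, accuracy / F1 / G-mean, AUROC with DeLong's standard error,
  Spearman correlation with MMSE, and subgroup AUROCs within each amyloid
  reading stratum.
- **Synthetic cohorts**: a generator emulating the joint structure of a
  dual-phase FBB study — gamma-variate perfusion TACs with cortical
  hypoperfusion in AD, bimodal amyloid SUVr by reading, discordant
  subgroups, and group-specific MMSE — so the whole pipeline is testable
  without clinical data.

The network and its training loop run on a small reverse-mode autodiff core
(`dualpet._autodiff`, numpy-based) whose gradients are verified against
finite differences in the test suite.

## Worked example

```python
import numpy as np
from dualpet import (CohortSpec, generate_cohort, cohort_summary, build_features,
                     stratified_split, ModelConfig, train_model, metrics_report)

spec = CohortSpec(seed=42)               # reference design: 74 CN / 190 AD
records = generate_cohort(spec)
summary = cohort_summary(records)
print(f"cohort: {summary['total']} subjects, "
      f"{summary['pct_abpos_cn']:.2f}% Ab+ CN, {summary['pct_abneg_ad']:.2f}% Ab- AD")

split = stratified_split(records, seed=42)
parts = {p: build_features([r for r in records if split.assignment[r.subject_id] == p])
         for p in ("train", "validation", "test")}

config = ModelConfig(seed=42, lr=1e-3, max_epochs=300,
                     early_stop_patience=100, lr_decay_patience=50)
model = train_model(parts["train"], parts["validation"], config, phase="dual")
scores = model.predict_scores(parts["test"])

report = metrics_report(scores, parts["test"].y,
                        readings=parts["test"].ab, mmse=parts["test"].mmse)
print(f"test AUROC {report.auroc:.3f} (SE {report.auroc_se:.3f}), "
      f"ACC {report.accuracy:.3f}, F1 {report.f1:.3f}, G-mean {report.g_mean:.3f}")
print(f"Spearman rho with MMSE: {report.spearman_rho:.3f}")
```

Output:

```
cohort: 264 subjects, 20.27% Ab+ CN, 16.84% Ab- AD
test AUROC 0.887 (SE 0.051), ACC 0.873, F1 0.917, G-mean 0.784
Spearman rho with MMSE: -0.426
```

The cohort composition lines are exact consequences of the stratum counts
(15/74 amyloid-positive CN, 32/190 amyloid-negative AD). The test metrics say
the dual-phase model separates AD from CN well on this synthetic cohort, and
its positivity score correlates negatively with cognition (higher score, lower
MMSE), as it should when the score tracks disease.

A command-line interface mirrors the library:

```sh
dualpet simulate --out cohort/ --seed 1
dualpet split --features cohort/ --seed 1 --out split.json
dualpet train --features cohort/ --split split.json --phase dual \
        --max-epochs 300 --lr 0.001 --patience 100 --out model.ckpt
dualpet predict --model model.ckpt --features cohort/ --out scores.csv
dualpet evaluate --scores scores.csv --meta cohort/meta.csv --out report.json
```

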