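# rccgrade

Noise- and imbalance-aware deep learning for **binary Fuhrman grading of
clear-cell renal cell carcinoma (ccRCC)** from per-patient stacks of 2-D
tumor ROI images. Intended for researchers studying weakly-labeled medical
image classification: the package provides the full method as a tested,
backbone-agnostic library plus CLI, exercised end to end on a bundled
synthetic cohort generator (the motivating clinical CT data are private).

## The method

Patients carry a Fuhrman grade (I–IV); grades I–II form the low-grade class
(y = 0), III–IV the high-grade class (y = 1). Every image inherits its
patient's label. Four components address the data pathologies of this task:

* **Rotation-pretext pretraining.** Each development image is expanded into
  its four clockwise quarter-turns labeled k ∈ {0,1,2,3}; a backbone +
  linear head learns to predict k (plain CE, SGD). The backbone is then
  transferred to the grading model, avoiding natural-image pretraining's
  domain shift.
* **Mixed loss against one-directional label noise.** Some high-labeled
  images are truly low-grade (rate α, default 0.4); low labels are trusted.
  With p_ij the predicted probability of class j and l_ij the one-hot label,

      L_mix = α · [−(1/N) Σ_i Σ_j l_ij log p_ij] + (1−α) · [−(1/N) Σ_i l_i0 log p_i0]

* **Class-frequency reweighting.** Per-class weights λ_j (inverse-frequency
  by default) scale each sample's contribution; the combined objective is

      L_total = −α(1/N) Σ_i Σ_j λ_j l_ij log p_ij − (1−α)(1/N) Σ_i λ_0 l_i0 log p_i0

* **Patient-level max aggregation and AUC-weighted ensembling.** Per-image
  scores collapse to G_i = max(g_1,…,g_M); K models combine as
  F_i = Σ_k γ_k G_ik / Σ_k γ_k with decile-stripped AUC weights
  (e.g. development AUCs 0.864, 0.822, 0.830, 0.859 → γ = 0.064, 0.022,
  0.030, 0.059).

Training: SGD, 5-epoch linear warm-up to lr 0.1 then cosine decay, backbone
at 0.1× the projection head's rate, weight decay 1e-4, quarter-turn/flip
augmentation. The backend is a compact numpy engine with hand-derived,
finite-difference-verified gradients; backbones are pluggable through a
registry. See `docs/methods.md` for the full account.

## Worked example

The scaled component analysis on the bundled synthetic cohort — 80 patients
(60 development / 20 validation by acquisition year), ~17 images/patient,
40% high-grade, patient-level label noise at rate 0.4 — across 5 training
seeds:

```python
from rccgrade.experiment import run_ablation
res = run_ablation(1, n_seeds=5)
print(res["medians"])
print(res["ensemble"]["weights"], res["ensemble"]["auc"])
```

prints (medians over seeds, metrics on the validation cohort at threshold
0.5; shown here rounded to 3-4 significant digits):

```
{'base':    {'auc': 0.865, 'acc': 60.0, 'sen':  0.0, 'spc': 100.0},
 'pretext': {'auc': 0.865, 'acc': 80.0, 'sen': 87.5, 'spc':  75.0},
 'loss':    {'auc': 0.844, 'acc': 60.0, 'sen':  0.0, 'spc': 100.0},
 'full':    {'auc': 0.865, 'acc': 80.0, 'sen': 75.0, 'spc':  83.3}}
[0.0573, 0.0098, 0.0855, 0.0881] 0.9375
```

Reading: all configurations rank patients well (AUC ≈ 0.84–0.87 on this
separable phantom), pretext initialization fixes the score calibration that
plain CE training leaves below the 0.5 operating point (sensitivity 0 → 87.5
on the minority high-grade class), and the 4-model decile-weighted ensemble
(AUC 0.9375) beats its weakest member (0.8125). These are directional,
desk-scale results on synthetic data, not clinical performance claims.

The same pipeline is scriptable from the shell:

```bash
rccgrade synth --n-patients 80 --seed 1 --out cohort/
rccgrade split cohort/manifest.csv --cutoff-year 2018 --out-dir splits/
rccgrade pretrain splits/development.csv --seed 1 --out pretext.npz
rccgrade develop splits/development.csv --init-from pretext.npz --seed 1 --out model.npz
rccgrade evaluate splits/validation.csv --model model.npz --out preds.csv
rccgrade ensemble p1.csv p2.csv p3.csv p4.csv --aucs 0.86,0.82,0.83,0.86 --out ens.csv
rccgrade ablate --seed 1 --out ablation/
```

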