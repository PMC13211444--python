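# pcrfusion

Multimodal prediction of pathological complete response (pCR) to
neoadjuvant chemotherapy in breast cancer, fusing a 3D DCE-MRI volume with
seven clinical features (age, race, ER, PR, HR, HER2, molecular subtype).
The package is aimed at researchers studying multimodal fusion for
treatment-response prediction who want a fully inspectable, CPU-scale
implementation with a synthetic-cohort harness instead of protected
patient data.

## What it implements

The classifier couples four components:

1. **Modality encoders** — a volumetric patch transformer whose
   LayerNorm-ed CLS state is the global imaging feature
   `f_img ∈ R^{C_hid}`, and a two-stage clinical MLP producing
   `f_clin ∈ R^256` via `z1 = LayerNorm(ReLU(x W1 + b1)) ∈ R^128`.
2. **Bidirectional cross-modal attention fusion** — both features are
   projected into a shared 512-dim space; two parallel multi-head
   cross-attention pathways (imaging-as-query and clinical-as-query, with
   distinct parameters) exchange semantics, and the attended vectors are
   concatenated and projected into the fused feature `f_fused ∈ R^512`.
3. **Contrast-aware feature enhancement** — sigmoid-gated modal
   calibration, clinical-semantic feature selection
   (`f ⊙ Softmax(ReLU(LayerNorm(W_s f_clin + b_s)))`), dual-path
   refinement with activation modulated by `(1 − β·s_intra)·α`, and
   projection to a 128-dim contrastive embedding `z`.
4. **Dual loss** — class-weighted cross-entropy on the classifier head
   plus a supervised contrastive loss over scaled similarities
   `S_ij = z_i·z_j/τ`, combined as `L_total = L_cls + λ·L_CL`
   (defaults τ = 0.1, λ = 0.9).  The intra-class similarity
   `s_intra,i = mean_{j∈P(i)} S_ij` feeds back into the enhancement stage.

Everything — including the transformer, attention, and AdamW with cosine
annealing — runs on a small NumPy reverse-mode autodiff engine
(`pcrfusion.autodiff`) that is property-tested against finite differences.

Since the real cohorts (ISPY1, MAMA-MIA) are external, a seeded
synthetic-cohort module generates tumor phantoms, dependent clinical
tables with realistic class imbalance (~29% pCR) and ER/PR missingness
(~67%), and labels from a logistic model with a planted imaging×HER2
interaction, so that fusion genuinely has something to gain over either
modality alone.

## Worked example

```python
import pcrfusion as pf
from pcrfusion.training import DESK_PROFILE, run_crossval

volumes, clinical, labels, truth = pf.generate_cohort(
    pf.CohortSpec(n=151, seed=0), pf.PhantomSpec()
)
result = run_crossval(dict(DESK_PROFILE), volumes, clinical, labels, k=5, seed=0)
print(result["table"].round(4))
```

prints (desk-scale profile: (32,32,16) volumes, 10 epochs, ~1 min on CPU):

```
           AUC     ACC     SEN     SPE      F1     PPV     NPV
fold_1  0.7172  0.6129  0.4444  0.6818  0.4000  0.3636  0.7500
fold_2  0.5979  0.6000  0.2222  0.7619  0.2500  0.2857  0.6957
fold_3  0.9148  0.8333  0.5000  0.9545  0.6154  0.8000  0.8400
fold_4  0.5625  0.6667  0.3750  0.7727  0.3750  0.3750  0.7727
fold_5  0.8239  0.7667  0.5000  0.8636  0.5333  0.5714  0.8261
mean    0.7232  0.6959  0.4083  0.8069  0.4347  0.4792  0.7769
```

Each fold row is the held-out test metrics of one stratified fold; the
summary (`result["summary"]["AUC"]`) gives 0.7232 ± 0.1330 with a Student-t
95% CI of (0.5581, 0.8883).  At this cohort size the fold spread is large —
that is the point of reporting the population SD and t-interval rather
than a single number.

The same pipeline is scriptable from the shell:

```bash
pcrfusion simulate --n 151 --seed 0 --out cohort/
pcrfusion crossval --data cohort/ --k 5 --out results/
pcrfusion sweep --data cohort/ --out results/sweep.csv   # tau x lambda grid
```

Ablation switches (`fusion=concat|igc|cgi|bicma`,
`mcfe=full|off|conventional_cl|no_calibration|no_dual_path|
no_dynamic_activation`, `modality=both|image|clinical`) are estimator
parameters, so unimodal baselines and component ablations reuse the exact
same codepaths.

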