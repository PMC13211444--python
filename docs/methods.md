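# Methods

`pcrfusion` implements a multimodal classifier for predicting pathological
complete response (pCR) to neoadjuvant chemotherapy in breast cancer from a
3D DCE-MRI volume and seven clinical features (age, race, ER, PR, HR, HER2,
molecular subtype).  Because the real cohorts it is designed around are
external, the package ships a synthetic phantom-cohort generator that
emulates their statistical structure, and every claim the test suite makes
is about behaviour on those synthetic cohorts or about closed-form
arithmetic.

## Model

**Encoders.**  The imaging encoder is a volumetric patch transformer: the
single-channel volume is cut into non-overlapping `p^3` patches, linearly
embedded, prepended with a learned CLS token, given learned positional
embeddings, and passed through pre-norm transformer blocks; the global
imaging feature is the LayerNorm of the final CLS state,
`f_img ∈ R^{C_hid}`.  No pretrained weights exist at any scale; depth,
heads, patch size and `C_hid` are configuration.  The clinical encoder is a
two-stage MLP: `z1 = LayerNorm(ReLU(x W1 + b1)) ∈ R^128`, refined
analogously into `f_clin ∈ R^256`.

**Bidirectional cross-modal attention fusion.**  Both features are
projected into a shared `d_fuse = 512` space; two parallel multi-head
cross-attention pathways with *distinct* parameters run in opposite
directions (imaging-as-query and clinical-as-query); the attended vectors
are concatenated and projected into the fused feature
`f_fused ∈ R^512`.  Because each modality is a pooled single-token
sequence, each head's post-softmax attention weight over the key axis is
identically 1, making the attended output independent of the query, and the
pooled per-sample attention summaries `a_mri`/`a_clin` constant.  The
module implements this literal form by default and additionally offers
`pooled="pre_softmax_sigmoid"` (sigmoid of the head-averaged scaled logit),
which is sample-dependent; neither is asserted as the "intended" reading,
and the ablation harness can compare both.

**Contrast-aware enhancement.**  The fused feature is (1) calibrated by
scalar sigmoid gates driven by `a_mri`/`a_clin` — algebraically
`(w_mri + w_clin) ⊙ f_fused`, an identity the tests verify; (2) masked by a
softmax feature-selection weight generated from `f_clin`; (3) refined by
two independently parameterized Linear+LayerNorm+ReLU paths whose
activations are modulated by `(1 − β·s_intra)·α`; and (4) projected to the
128-dim contrastive embedding as the average of the two path projections.
`s_intra` (the mean scaled similarity of a sample to its same-label batch
peers) is defined on the embedding that itself depends on the modulation,
so the forward pass is circular.  We resolve it with a two-pass scheme:
pass 1 computes a provisional embedding at `s_intra = 0`; the similarity is
computed from it and *detached from the gradient graph*; pass 2 recomputes
the modulated stages.  Inference uses `s_intra = 0`.  A finite-difference
test verifies the detachment contract.  `s_intra` is used raw (it scales
like `1/τ` and is unbounded); `β` initializes at 0.1 and `α` at 1.0, so the
model starts near the no-feedback regime, and `(1 − β·s_intra)` is not
clamped by default (a flag enables clamping at zero).

**Objectives.**  The classifier head (MLP 512→128→2, softmax) is trained
with class-weighted cross-entropy whose weights are the raw *opposite*
class counts of the training split (`w1 = #non-pCR`, `w0 = #pCR`); a flag
normalizes them by their mean.  The contrastive loss is supervised
contrastive over raw scaled dot products `S_ij = z_i·z_j/τ` (no L2
normalization by default; a flag enables the cosine variant).  Anchors with
no same-label peer are skipped; the denominator runs over all non-self
samples; log-sum-exp uses a detached max shift with the self-term masked
before exponentiation.  The total loss is `L_cls + λ·L_CL` with defaults
`τ = 0.1`, `λ = 0.9`.

## Synthetic cohorts

The generator emulates three properties of real pCR cohorts: (a) 3D
tumor-bearing volumes — an ellipsoidal lesion at mean contrast +2.0 with
within-tumor Gaussian heterogeneity (SD per patient ~ U(0.1, 0.9)) over a
Gaussian background (SD 0.2); (b) a clinical table with realistic
dependencies (PR tracks ER 80% of the time, HR = ER∨PR, subtype determined
by HR/HER2) and per-feature missingness matching a large multicenter cohort
(ER/PR 66.8%, all other features <2%); and (c) a logistic label model

    p = σ(b0 + β_img·s + β·x + γ·s·HER2),   s = z(volume fraction) + z(heterogeneity)

with defaults `β_img = 0.8`, `β_ER = −0.6`, `β_HER2 = 0.5`, `γ = 1.5`
(ER-negative tumors respond more often; the interaction is planted on HER2
to mirror HER2-linked chemosensitivity).  The intercept is solved by
bisection so the expected event rate hits the target (default 28.5%,
matching the real class imbalance).  Missingness is injected *after* label
generation.  Everything is bit-reproducible under a fixed seed.

What the generator does **not** emulate: DCE contrast kinetics, scanner
artifacts or bias fields, spatial resampling, DICOM metadata, or
correlations between imaging morphology and receptor status.  Passing tests
therefore demonstrate that the architecture can learn a planted
imaging×clinical interaction and that its arithmetic is correct — not that
it attains any particular performance on real MRI.

## Training and evaluation

Training uses AdamW (weight decay 0.01) with a single-cycle cosine
annealing schedule and layer-wise learning rates (`lr_encoder` for the
imaging encoder, `lr_other` elsewhere; defaults 1e−5 / 1e−4, batch 4,
50 epochs).  The desk-scale profile used by the test suite and the
experiment scripts (`training.DESK_PROFILE`) is the package's own choice of
problem size: volumes (32,32,16), `C_hid = 32`, depth 1, `d_fuse = 64`,
batch 16, 10 epochs, and a uniform learning rate of 1e−3 — the low encoder
rate in the full-scale default exists to protect *pretrained* encoder
weights, and this package's encoder is always trained from scratch, so the
desk profile has no reason to slow it down.  Larger batches also give the
contrastive loss more in-batch positives at desk scale.

Evaluation reports AUC (tie-corrected rank statistic), ACC, SEN, SPE, F1,
PPV, NPV; zero-denominator metrics are flagged undefined rather than
silently zeroed.  Cross-validation is stratified k-fold (default 5);
fold summaries use the **population** SD (denominator k) — the convention
under which the reference fold table's printed mean ± SD is reproduced
exactly — with the sample convention behind a flag, and 95% CIs from
Student's t with k−1 degrees of freedom.  Bootstrap CIs are non-stratified
percentile case resampling (default 1000 iterations) with undefined
resamples redrawn and counted.  DeLong's test uses the midrank
structural-components formulation; zero variance of the AUC difference
returns p = 1 by convention.

## Numerical choices and conventions

- All computation is float64 on a small reverse-mode autodiff engine;
  gradients are property-tested against central finite differences.
- LayerNorm of an all-constant vector returns zeros (epsilon-stabilized),
  keeping encoders total on degenerate inputs.
- Padding with an odd remainder puts the extra voxel on the high-index
  side; cropping removes it from the high side.  Pad/crop is idempotent.
- Volume Z-scoring is over the whole volume, not tumor-masked.
- Age SD uses the sample (n−1) convention for feature scaling (flag for
  population); age statistics are fitted on training rows only.
- Hard labels are the argmax of the two softmax outputs (threshold 0.5).
- Per-cell sweep seeds derive from the base seed plus the cell index.

## Known limitations

- The literal pooled attention summaries are constant 1, so modal
  calibration receives no per-sample signal under the default mode; the
  sigmoid-of-logit mode is the documented alternative.
- Ablation orderings at desk scale are stochastic; the suite asserts only
  the seeded median multimodal-vs-unimodal ordering, not per-ablation
  monotonicity.
- The raw (unnormalized) contrastive similarities grow like `1/τ`, which
  makes loss magnitudes large; AdamW's per-parameter scaling absorbs this,
  but loss values across configurations are not directly comparable.
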